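# Methods

This note records the model, the conventions that make results
bit-reproducible, the synthetic-data design, and the choices made where
the design was genuinely open.

## Problem setting

Radial-probe EBUS yields a circular ultrasound field centred on the probe,
with the lesion wrapped around the centre. The classification target is
the biopsy-derived case label (benign / malignant). Data arrive as
per-case frame stacks with a manifest carrying, for every frame: case id,
label, probe-centre pixel coordinates and a pixels-per-cm calibration.
Splits are always case-level; metrics are image-level.

## Geometric preprocessing

Conventions are fixed once: (row, col) coordinates, 0-based, half-open
ranges.

* **Crops.** Type k covers a square physical field (4/3/2/1 cm for
  k=1..4); side in pixels is `round(side_cm * pixels_per_cm)` (half-up).
  The crop spans `[center - side//2, center - side//2 + side)` on both
  axes, so for even sides the probe lands on crop index `side//2`. Crops
  never resample; a crop that would leave the frame raises a geometry
  error reporting the overhang in pixels.
* **Polar transform.** Output pixel (i, j) samples the input at radius
  `r = (i+0.5)/n_radius * r_max` and angle `theta = (j+0.5)/n_angle * 2*pi`
  measured from the +col direction toward +row; rows index radius
  outward, columns index angle over the full turn. Nearest interpolation
  rounds half-up per axis; bilinear uses order-1 interpolation with edge
  clamping at the half-pixel border. `r_max` may not exceed the probe
  centre's distance to the nearest image edge (plus half a pixel); there
  is no padding mode — out-of-field requests fail loudly. When unwrapping
  a probe-centred crop the pipeline sets `r_max` to the centre-to-edge
  pixel distance of the crop.
* **Gray conversion** uses BT.601 luma (0.299, 0.587, 0.114), rounded
  half-up to 8 bits, and happens before resizing. **Resizing** is
  bilinear (pixel-center convention) and an exact identity when the size
  already matches.
* **Multi-scale composites** assign R/G/B to the three source types in
  ascending type id. The assignment is arbitrary up to a channel
  permutation the encoder can absorb; fixing one makes composites
  reproducible and channel readback exactly invertible.

## Models

* **Encoders.** A backbone CNN emitting an NCHW feature map, global
  average pooling, and a three-layer head: FC -> BN -> ReLU -> Dropout,
  repeated twice, then FC to 2 logits. BN+Dropout follow each hidden FC
  block and not the output layer (dropout after logits would be
  meaningless). Dropout defaults to p=0.5; head widths default per
  backbone (tiny_cnn: 32 -> 64 -> 32 -> 2). The registry ships two scratch
  backbones — `tiny_cnn` (three stride-2 conv-BN-ReLU stages, ~10k
  parameters) and `small_cnn` (four stages) — sized so the full pipeline
  trains on one CPU core in minutes; any module emitting an NCHW map can
  be registered. Feature extraction taps the last convolutional block
  (before pooling); "FC features" tap the post-ReLU activation of the
  second head block (width h2). Both run gradient-free in evaluation mode
  and never mutate parameters.
* **CBAM** is the standard two-stage gate: channel attention via a shared
  two-layer MLP over global-average and global-max descriptors
  (sigmoid-gated), then spatial attention via a 7x7 convolution over the
  stacked channel-mean/max maps. Gates lie in (0,1), so outputs never
  exceed inputs in magnitude.
* **MHSA over a map** treats the h*w spatial positions as tokens with the
  channel axis as embedding, no positional encoding — parameter count is
  then independent of spatial extent, and the operation is
  permutation-equivariant in the tokens. Head count defaults to the
  largest of {8,4,2,1} dividing the embedding width, which is valid for
  any branch combination.
* **Fusion variants.** v1: `F'' = MHSA(concat_k(F_k + CBAM(F_k)))` — the
  residual sits around CBAM only. v2: `F'' = X + MHSA(X)`. v3: v2's map
  path pooled to a vector, concatenated with a parallel
  token-MHSA-with-residual over the per-branch FC features; the two
  attention paths have independent parameters. Pooling the map path
  before the final concatenation is this package's choice so the
  classifier always sees a fixed-width vector. All variants accept 2-4
  branches. Branch maps with unequal spatial grids are adaptively
  average-pooled to the smallest grid (pooling, not interpolation, for
  determinism).
* **Classifier:** adaptive average pool -> flatten -> BN -> FC(2);
  vector input skips the pooling.

## Training protocol

One hyperparameter set for both stages: Adam with L2 weight decay 5e-4
(decay added to the raw gradient), lr 1e-3, batch size 32, up to 200
epochs, inputs scaled to [0,1]. Early stopping uses patience 6 and
restores the best checkpoint; the monitored quantity is validation AUC
with validation loss as tie-breaker (lexicographic), falling back to the
loss alone when the validation split holds one class. The tie-break
matters on easily separable data: AUC saturates within a few epochs, and
continuing while the loss improves returns a checkpoint whose 0.5
threshold is actually calibrated. Monitoring the loss alone was tried
first and proved degenerate on
overlapping-class cohorts: small overconfident models drive the weighted
validation loss *up* from its prior-matching value at initialization even
while ranking quality climbs steadily, so loss-based selection restores a
near-random checkpoint. AUC is also the method's designated primary
metric, which makes it the natural selection criterion. Augmentation draws one
transform per frame group — horizontal/vertical flips, k*90-degree
rotation, brightness/contrast/saturation factors uniform in ±20% — and
applies it identically to every branch image of the group, after the
geometric preprocessing. Stage 2 freezes all encoder parameters
(bit-exactly, verified by test) and optimizes only fusion + classifier.
When nothing is trainable the epoch pass is evaluation-only.

Loss weights come from *case* counts in the training split, not image
counts: normalize the counts, take reciprocals, renormalize —
algebraically `w_b = N_m/(N_b+N_m)`. The weights enter cross-entropy as
per-class multipliers under mean reduction; with equal weights the loss
is exactly half the unweighted cross-entropy.

## Evaluation

Malignant is positive; threshold-dependent metrics use 0.5 on the
softmax malignancy probability. AUC follows the Mann-Whitney convention
(ties count one half) and equals the trapezoidal ROC area; it is the
primary metric. Undefined ratios surface as NaN with a warning — silent
zeros would corrupt cross-fold means. Cross-validation makes four
stratified case-level test folds; the non-test cases split per class with
about one third held for validation (mirroring a 6/3/4 benign and
40/21/21 malignant division at the clinical cohort's size). Fold metrics
are averaged unweighted. A fixed single-split mode (the first fold) is
also supported, used by the disk pipeline.

## Synthetic phantom

The generator emulates what the pipeline needs from real radial EBUS, not
ultrasound physics: a dark probe disk at a recorded centre with cm
calibration on a 256-px frame at 50 px/cm (so a 4x4 cm Type-1 crop
fits), one lesion centred near the probe (radius 0.5-0.9 cm),
multiplicative log-normal speckle (scale 0.12), and class-conditioned
lesion appearance. Benign lesions are homogeneous hypoechoic disks with
circular boundaries; malignant lesions carry band-limited sinusoidal
interior texture (six components, spatial frequency 0.5-1.2 rad/px,
summed amplitude 45 gray levels) and a radially perturbed boundary (four
harmonics, total relative amplitude 0.10). The texture frequency band is
chosen so the malignant heterogeneity dominates the mean absolute radial
intensity gradient inside the lesion annulus — a model-free 1-D score
whose class-separation AUC the tests verify (> 0.9 across seed suites).
Frames of one case share geometry and texture and differ by ±2 px / ±0.1
rad pose jitter; speckle is redrawn per frame. All draws derive from
explicit seeds (case streams from the cohort seed, frame streams from
(case seed, frame index)), so regeneration is byte-identical.

The default cohort is 13 benign / 82 malignant cases with 12 frames each
(1140 frames), the imbalance and size of the clinical archives this kind
of study works with. `class_contrast < 1` makes each case's appearance
strength a clipped-normal draw around its class value (sigma =
0.5*(1-contrast)), producing genuinely ambiguous cases.

What the phantom does **not** model: point-spread functions, attenuation,
shadowing, real sonographic texture statistics, burned-in overlays, or
scale marks (calibration travels in the manifest). Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
its components behave as designed under a controlled, learnable contrast
— not that the learned features transfer to clinical EBUS.

## Study problem sizes

The canned studies in `m3net.experiments` are sized for a single CPU
core. Fusion study: 60 cases (12 benign / 48 malignant, ~6:1), 5 frames
per case, 32-px branch images (`type4` and `polar3`), tiny_cnn encoders,
FFM-v2, at most 40 epochs per stage. Imbalance study: 84 cases (12/72,
6:1) at class_contrast 0.2, 6 frames per case, one branch, trained twice
(case weights vs flat weights). The overlap cohort is larger per class
than the fusion cohort so the per-class validation signal that drives
early stopping is estimated from more than a couple of cases, and its
contrast is low enough that a sizeable fraction of cases is genuinely
ambiguous — the regime where the unweighted model's majority-class bias
(sensitivity far above specificity) appears and the case-weighted loss
has something to correct. Weighting can over-correct toward the minority
class on individual seeds; the study's claim is about the median gap
ordering, not every run.

## Known limitations

* The scratch backbones stand in for large pretrained CNNs; no pretrained
  weights are bundled, and `pretrained=True` is rejected.
* The polar convention (full 2-pi sweep, rows = radius, angle origin and
  direction) is a documented package choice; other conventions differ by
  a column roll/flip the encoder can absorb.
* Training determinism is exact only on one platform/BLAS build;
  histories are reproducible bit-for-bit under a fixed seed in-process.
* The weighted-vs-flat comparison is a qualitative property (gap ordering
  in the median), not an effect-size claim; individual seeds can stop
  early on a plateau and degenerate to single-class prediction.
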