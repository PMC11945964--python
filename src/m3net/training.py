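"""Two-stage training with case-count-weighted cross-entropy.

Stage 1 fine-tunes one CNN per image branch on its own image variant.
Stage 2 freezes those encoders and trains only the fusion module and
classifier on the frozen features.  Both stages share one hyperparameter
set: Adam with weight decay 5e-4, learning rate 1e-3, batch size 32, up to
200 epochs with early stopping (patience 6, monitored on validation AUC,
best checkpoint restored), inputs scaled from [0, 255] to [0, 1], and
augmentation by horizontal/vertical flips, 90-degree rotations and random
brightness/contrast/saturation jitter applied identically to every image
of a frame group.

Class imbalance is handled by loss weights derived from *case* counts in
the training split (not image counts): counts are normalized, their
reciprocals taken so weights are inversely proportional to case counts,
and the reciprocals renormalized — algebraically
``w_b = n_m / (n_b + n_m)``, ``w_m = n_b / (n_b + n_m)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from . import _nn as nn
from .encoders import Encoder, EncoderConfig, build_encoder
from .errors import ConfigurationError, DataError
from .fusion import FusionConfig, FusionHead, align_branches
from .multiscale import MultiScaleSpec, generate_multiscale
from .phantom import CaseRecord, LABELS
from .preprocess import CropSpec, PolarSpec, slbic_crop, polar_transform, \
    to_grayscale, resize_to


# -- class weights ------------------------------------------------------------

@dataclass(frozen=True)
class ClassWeights:
    """Loss weights derived from benign/malignant case counts."""

    n_b: int
    n_m: int
    w_b: float
    w_m: float

    def as_array(self) -> np.ndarray:
        return np.array([self.w_b, self.w_m])


def compute_class_weights(n_b: int, n_m: int) -> ClassWeights:
    """Four-step derivation: normalize counts, invert, renormalize."""
    if n_b < 1 or n_m < 1:
        raise ValueError(f"case counts must be >= 1, got ({n_b}, {n_m})")
    total = n_b + n_m
    nb_norm, nm_norm = n_b / total, n_m / total
    rb, rm = 1.0 / nb_norm, 1.0 / nm_norm
    return ClassWeights(n_b=n_b, n_m=n_m, w_b=rb / (rb + rm), w_m=rm / (rb + rm))


def weighted_cross_entropy(logits, labels, weights) -> nn.Tensor:
    """Mean over the batch of ``w_class(y) * (-log softmax(logits)[y])``."""
    logits = logits if isinstance(logits, nn.Tensor) else nn.Tensor(logits)
    labels = np.asarray(labels)
    if logits.ndim != 2 or logits.shape[1] != 2:
        raise ValueError(f"logits must be (batch, 2), got {logits.shape}")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must lie in {0 (benign), 1 (malignant)}")
    if isinstance(weights, ClassWeights):
        w = weights.as_array()
    else:
        w = np.asarray(weights, dtype=np.float64)
    shifted = logits - nn.Tensor(logits.numpy().max(axis=1, keepdims=True))
    logp = shifted - shifted.exp().sum(axis=1, keepdims=True).log()
    onehot = np.eye(2)[labels]
    picked = (logp * nn.Tensor(onehot)).sum(axis=1)
    return (picked * nn.Tensor(-w[labels])).sum() * (1.0 / len(labels))


# -- augmentation -------------------------------------------------------------

def augment(group: list[np.ndarray], rng: np.random.Generator, *,
            hflip: bool = True, vflip: bool = True, rot90: bool = True,
            jitter: float = 0.2) -> list[np.ndarray]:
    """One random draw of flips/rotation/jitter applied to a frame group.

    Every image in ``group`` (CHW float arrays in [0, 1], all derived from
    the same frame) receives the *same* geometric transform and the same
    photometric factors, keeping the branches synchronized.  With all
    options disabled the group is returned unchanged.
    """
    do_h = hflip and rng.random() < 0.5
    do_v = vflip and rng.random() < 0.5
    k = int(rng.integers(0, 4)) if rot90 else 0
    if jitter > 0:
        br, co, sa = rng.uniform(1 - jitter, 1 + jitter, size=3)
    else:
        br = co = sa = 1.0
    out = []
    for img in group:
        x = img
        if do_h:
            x = np.flip(x, axis=2)
        if do_v:
            x = np.flip(x, axis=1)
        if k:
            x = np.rot90(x, k, axes=(1, 2))
        if jitter > 0:
            x = x * br
            x = x.mean() + (x - x.mean()) * co
            gray = x.mean(axis=0, keepdims=True)
            x = gray + (x - gray) * sa
            x = np.clip(x, 0.0, 1.0)
        out.append(np.ascontiguousarray(x))
    return out


# -- branch image assembly ----------------------------------------------------

def parse_branch(name: str) -> tuple[str, object]:
    """Normalize a branch name into (kind, spec).

    Accepted: ``type1..type4``, ``polar1..polar4``, and the six multi-scale
    names (``MS 2-3-4`` / ``ms234`` / ``pms-2-3-4`` ...).
    """
    norm = name.strip().lower().replace(" ", "").replace("-", "").replace("_", "")
    if norm.startswith("type") and norm[4:] in "1234" and len(norm) == 5:
        return "crop", CropSpec(int(norm[4]))
    if norm.startswith("polar") and norm[5:] in "1234" and len(norm) == 6:
        return "polar", CropSpec(int(norm[5]))
    if norm.startswith(("ms", "pms")):
        digits = norm.lstrip("pms")
        spaced = f"{'PMS' if norm.startswith('pms') else 'MS'} {'-'.join(digits)}"
        return "multiscale", MultiScaleSpec.from_name(spaced)
    raise ConfigurationError(f"unknown branch name {name!r}")


def _polar_of_crop(crop: np.ndarray, size: int) -> np.ndarray:
    side = crop.shape[0]
    center = (side // 2, side // 2)
    r_max = min(center[0], center[1], side - 1 - center[0], side - 1 - center[1])
    spec = PolarSpec(n_radius=size, n_angle=size, r_max_px=float(r_max),
                     interpolation="bilinear")
    return polar_transform(crop, center, spec)


def branch_image(frame: np.ndarray, record: CaseRecord, branch: str,
                 size: int) -> np.ndarray:
    """Build one branch input (HWC uint8, size x size) from a raw frame."""
    kind, spec = parse_branch(branch)
    if kind == "crop":
        crop = slbic_crop(frame, record.probe_center_px, record.pixels_per_cm, spec)
        return resize_to(crop, (size, size))
    if kind == "polar":
        crop = slbic_crop(frame, record.probe_center_px, record.pixels_per_cm, spec)
        return _polar_of_crop(crop, size)
    gray = {}
    for t in spec.source_types:
        crop = slbic_crop(frame, record.probe_center_px, record.pixels_per_cm,
                          CropSpec(t))
        if spec.polar:
            crop = _polar_of_crop(crop, size)
        gray[t] = resize_to(to_grayscale(crop), (size, size))
    return generate_multiscale(gray, spec).pixels


@dataclass
class BranchDataset:
    """Per-branch image stacks aligned frame-by-frame across branches."""

    branches: tuple[str, ...]
    images: dict[str, np.ndarray]        # branch -> (N, 3, s, s) float in [0,1]
    labels: np.ndarray                   # (N,) int, 0 benign / 1 malignant
    case_ids: list[str]
    n_cases: dict[str, int]              # per-class CASE counts


def build_dataset(records: list[CaseRecord], branches: tuple[str, ...],
                  size: int, frame_indices=None) -> BranchDataset:
    if not records:
        raise DataError("empty case list")
    stacks: dict[str, list] = {b: [] for b in branches}
    labels, case_ids = [], []
    for rec in records:
        frames = rec.load_frames()
        idx = frame_indices(len(frames)) if frame_indices else range(len(frames))
        for i in idx:
            for b in branches:
                img = branch_image(frames[i], rec, b, size)
                stacks[b].append(img.astype(np.float64).transpose(2, 0, 1) / 255.0)
            labels.append(rec.label_index)
            case_ids.append(rec.case_id)
    n_cases = {lab: sum(1 for r in records if r.label == lab) for lab in LABELS}
    return BranchDataset(
        branches=tuple(branches),
        images={b: np.stack(v) for b, v in stacks.items()},
        labels=np.asarray(labels), case_ids=case_ids, n_cases=n_cases)


# -- configuration ------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 5e-4
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 6
    input_size: int = 224
    seed: int = 0
    augment: bool = True
    jitter: float = 0.2

    def validate(self) -> None:
        if min(self.lr, self.weight_decay, self.batch_size, self.max_epochs,
               self.early_stop_patience, self.input_size) <= 0:
            raise ConfigurationError("all training hyperparameters must be positive")
        if self.early_stop_patience >= self.max_epochs:
            raise ConfigurationError("patience must be smaller than max_epochs")


# -- training loops -----------------------------------------------------------

def _scores_from_logits(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e[:, 1] / e.sum(axis=1)


def _auc_or_nan(scores, labels) -> float:
    from .evaluation import compute_auc
    if len(set(np.asarray(labels).tolist())) < 2:
        return float("nan")
    return compute_auc(scores, labels)[0]


def _evaluate(forward, images_per_branch, labels, weights, batch_size):
    losses, scores = [], []
    n = len(labels)
    with nn.no_grad():
        for lo in range(0, n, batch_size):
            sl = slice(lo, lo + batch_size)
            logits = forward([x[sl] for x in images_per_branch])
            losses.append(weighted_cross_entropy(logits, labels[sl], weights).numpy()
                          * (min(n, lo + batch_size) - lo))
            scores.append(_scores_from_logits(logits.numpy()))
    return float(np.sum(losses) / n), np.concatenate(scores)


def _fit(model: nn.Module, trainable, forward_train, forward_eval,
         train_ds: BranchDataset, valid_ds: BranchDataset,
         weights: ClassWeights, config: TrainConfig):
    """Shared epoch loop: minibatch SGD with patience-based early stopping.

    Model selection is lexicographic on (validation AUC, -validation
    loss): AUC — the primary metric — decides, and the loss breaks ties
    so that once ranking saturates the better-calibrated checkpoint wins.
    When AUC is undefined (single-class validation split) only the loss
    acts.  Stopping occurs after `early_stop_patience` epochs without
    improvement, and the best checkpoint is restored.  Selecting on loss
    alone is degenerate here: on overlapping-class cohorts the weighted
    loss of the trivial prior-matching model is a local optimum, so the
    restored checkpoint would be the near-random initial one even while
    ranking quality climbs.
    """
    config.validate()
    if len(train_ds.labels) == 0 or len(valid_ds.labels) == 0:
        raise DataError("train and validation splits must be non-empty")
    opt = nn.Adam(trainable, lr=config.lr, weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 77]))
    history: list[dict] = []
    best = {"score": (-np.inf, -np.inf), "state": None, "epoch": -1}
    train_x = [train_ds.images[b] for b in train_ds.branches]
    valid_x = [valid_ds.images[b] for b in valid_ds.branches]
    for epoch in range(config.max_epochs):
        epoch_loss, n_seen = 0.0, 0
        if trainable:
            model.train()
            perm = rng.permutation(len(train_ds.labels))
            for lo in range(0, len(perm), config.batch_size):
                idx = perm[lo:lo + config.batch_size]
                batches = [x[idx].copy() for x in train_x]
                if config.augment:
                    for j in range(len(idx)):
                        group = augment([x[j] for x in batches], rng,
                                        jitter=config.jitter)
                        for x, img in zip(batches, group):
                            x[j] = img
                logits = forward_train(batches)
                loss = weighted_cross_entropy(logits, train_ds.labels[idx], weights)
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.numpy()) * len(idx)
                n_seen += len(idx)
            model.eval()
            train_loss = epoch_loss / n_seen
        else:
            # nothing to optimize: the pass is evaluation-only
            model.eval()
            train_loss, _ = _evaluate(forward_eval, train_x, train_ds.labels,
                                      weights, config.batch_size)
        valid_loss, valid_scores = _evaluate(forward_eval, valid_x,
                                             valid_ds.labels, weights,
                                             config.batch_size)
        valid_auc = _auc_or_nan(valid_scores, valid_ds.labels)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "valid_loss": valid_loss, "valid_auc": valid_auc})
        auc_term = valid_auc if np.isfinite(valid_auc) else -np.inf
        score = (auc_term, -valid_loss)
        if score > best["score"]:
            best = {"score": score, "state": copy.deepcopy(model.state_dict()),
                    "epoch": epoch}
        elif epoch - best["epoch"] >= config.early_stop_patience:
            break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    model.eval()
    return history


def _case_weights(ds: BranchDataset) -> ClassWeights:
    return compute_class_weights(max(ds.n_cases["benign"], 1),
                                 max(ds.n_cases["malignant"], 1))


def train_stage1(branch: str, encoder_config: EncoderConfig,
                 train_records: list[CaseRecord], valid_records: list[CaseRecord],
                 config: TrainConfig, *,
                 weights: ClassWeights | None = None) -> tuple[Encoder, list[dict]]:
    """Fine-tune one encoder on one image branch; returns the best checkpoint."""
    if not train_records or not valid_records:
        raise DataError("stage-1 training needs non-empty train and valid splits")
    _check_disjoint(train_records, valid_records)
    train_ds = build_dataset(train_records, (branch,), config.input_size)
    valid_ds = build_dataset(valid_records, (branch,), config.input_size)
    nn.manual_seed(config.seed)
    encoder = build_encoder(encoder_config)
    if weights is None:
        weights = _case_weights(train_ds)

    def forward(batches):
        return encoder(nn.Tensor(batches[0]))

    history = _fit(encoder, encoder.parameters(), forward, forward,
                   train_ds, valid_ds, weights, config)
    return encoder, history


def train_stage2(encoders: dict[str, Encoder], fusion_config: FusionConfig,
                 train_records: list[CaseRecord], valid_records: list[CaseRecord],
                 config: TrainConfig, *,
                 weights: ClassWeights | None = None,
                 head: FusionHead | None = None) -> tuple[FusionHead, list[dict]]:
    """Train fusion + classifier on frozen encoder features."""
    if not train_records or not valid_records:
        raise DataError("stage-2 training needs non-empty train and valid splits")
    _check_disjoint(train_records, valid_records)
    branches = tuple(encoders)
    train_ds = build_dataset(train_records, branches, config.input_size)
    valid_ds = build_dataset(valid_records, branches, config.input_size)
    nn.manual_seed(np.random.SeedSequence([config.seed, 2]).generate_state(1)[0]
                   & 0x7FFFFFFF)
    if head is None:
        head = FusionHead(fusion_config)
    for enc in encoders.values():
        enc.eval()
        for p in enc.parameters():
            p.requires_grad = False
    if weights is None:
        weights = _case_weights(train_ds)

    def forward(batches):
        maps, fcs = [], []
        with nn.no_grad():
            for enc, xb in zip(encoders.values(), batches):
                x = nn.Tensor(xb)
                maps.append(enc.forward_features(x))
                if fusion_config.variant == "ffm_v3":
                    fcs.append(enc.forward_fc(x))
        maps = align_branches(maps)
        return head(maps, fcs if fusion_config.variant == "ffm_v3" else None)

    trainable = [p for p in head.parameters() if p.requires_grad]
    history = _fit(head, trainable, forward, forward,
                   train_ds, valid_ds, weights, config)
    return head, history


def _check_disjoint(*record_lists: list[CaseRecord]) -> None:
    seen: set[str] = set()
    for records in record_lists:
        ids = {r.case_id for r in records}
        overlap = seen & ids
        if overlap:
            raise DataError(f"case-level splits overlap: {sorted(overlap)}")
        seen |= ids


def predict_scores(model_forward, ds: BranchDataset,
                   batch_size: int = 32) -> np.ndarray:
    """Per-image malignancy probabilities from a branch-batch forward fn."""
    scores = []
    xs = [ds.images[b] for b in ds.branches]
    with nn.no_grad():
        for lo in range(0, len(ds.labels), batch_size):
            sl = slice(lo, lo + batch_size)
            logits = model_forward([x[sl] for x in xs])
            scores.append(_scores_from_logits(logits.numpy()))
    return np.concatenate(scores)
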