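"""Canned phantom experiments exercising the full pipeline.

Two desk-scale studies, used by the test suite and the reproduction
script alike:

* :func:`fusion_learnability` — a separable 60-case cohort (12 benign /
  48 malignant, mirroring the ~6:1 clinical case imbalance), two branches
  (the 1 x 1 cm crop and the polar-unwrapped 2 x 2 cm crop), stage-1
  encoders plus an FFM-v2 fusion head.  Reports held-out image-level AUC
  for the fused model and for each single branch.
* :func:`imbalance_mitigation` — an overlapping-class cohort at the same
  6:1 case imbalance, one branch, trained twice: with the case-count
  weights and with flat weights.  Reports the |sensitivity - specificity|
  gap of both models; weighting should shrink it.

Problem sizes (32 px branch images, small scratch CNN, <= 40 epochs) are
chosen so each experiment runs in minutes on a single CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import EncoderConfig
from .evaluation import evaluate_scores, make_fold_plan
from .phantom import PhantomConfig, simulate_cohort
from .pipeline import ExperimentSpec, make_forward, run_experiment
from .training import (ClassWeights, TrainConfig, build_dataset,
                       predict_scores, train_stage1)

def phantom_separability(seed: int, n_per_class: int = 60,
                         config: PhantomConfig = None) -> float:
    """AUC of a 1-D hand-crafted score separating phantom classes.

    The score is the mean absolute radial intensity gradient inside the
    lesion annulus (0.25-0.75 of the lesion radius) — heterogeneous
    malignant texture drives it up.  Serves as a model-free check that the
    generator's class contrast is real before any training happens.
    """
    from .evaluation import compute_auc
    from .phantom import _case_params, generate_phantom_frame

    config = config or PhantomConfig()
    scores, labels = [], []
    for k, label in enumerate(("benign", "malignant")):
        for i in range(n_per_class):
            case_seed = (seed * 100_000 + k * 50_000 + i) & 0x7FFFFFFF
            params = _case_params(config, label, case_seed)
            img = generate_phantom_frame(config, label, case_seed, 0)
            img = img[:, :, 0].astype(float)
            n = config.image_size_px
            rows, cols = np.mgrid[0:n, 0:n]
            lc = params["lesion_center"]
            r = np.hypot(rows - lc[0], cols - lc[1])
            radius = params["radius_px"]
            annulus = (r > 0.25 * radius) & (r < 0.75 * radius)
            gr, gc = np.gradient(img)
            radial = (gr * (rows - lc[0]) + gc * (cols - lc[1])) / np.maximum(r, 1e-9)
            scores.append(np.abs(radial)[annulus].mean())
            labels.append(k)
    return compute_auc(scores, labels)[0]


#: Conditions of the separable-cohort fusion study.
FUSION_COHORT = PhantomConfig(n_cases_benign=12, n_cases_malignant=48,
                              frames_per_case=5, seed=21)
#: Conditions of the overlapping-class imbalance study.
OVERLAP_COHORT = PhantomConfig(n_cases_benign=12, n_cases_malignant=72,
                               frames_per_case=6, class_contrast=0.2, seed=21)
#: Shared training settings for both studies (patience 6 early stopping).
STUDY_TRAIN = TrainConfig(input_size=32, max_epochs=40)


def _first_fold(records, seed):
    plan = make_fold_plan(records, n_folds=4, seed=seed)
    by_id = {r.case_id: r for r in records}
    fold = plan.folds[0]
    return ([by_id[i] for i in fold.train], [by_id[i] for i in fold.valid],
            [by_id[i] for i in fold.test])


@dataclass
class FusionStudyResult:
    fused_auc: float
    single_aucs: dict[str, float]
    n_test_images: int


def fusion_learnability(seed: int, cohort: PhantomConfig = FUSION_COHORT,
                        branches: tuple[str, str] = ("type4", "polar3"),
                        fusion_variant: str = "ffm_v2") -> FusionStudyResult:
    """Two-branch fused model vs its single branches on held-out cases."""
    records = simulate_cohort(cohort)
    train, valid, test = _first_fold(records, seed=cohort.seed)
    spec = ExperimentSpec(
        branches=branches,
        encoder_config=EncoderConfig(backbone_name="tiny_cnn"),
        fusion_variant=fusion_variant,
        train_config=TrainConfig(input_size=STUDY_TRAIN.input_size,
                                 max_epochs=STUDY_TRAIN.max_epochs, seed=seed))
    result = run_experiment(spec, train, valid, test)
    singles = {}
    for branch, enc in result.encoders.items():
        ds = build_dataset(test, (branch,), spec.train_config.input_size)
        scores = predict_scores(make_forward({branch: enc}, None, fusion_variant), ds)
        singles[branch] = evaluate_scores(scores, ds.labels).auc
    return FusionStudyResult(fused_auc=result.report.auc, single_aucs=singles,
                             n_test_images=len(result.labels))


@dataclass
class ImbalanceStudyResult:
    weighted_gap: float
    unweighted_gap: float
    weighted_auc: float
    unweighted_auc: float
    n_test_images: int


def imbalance_mitigation(seed: int,
                         cohort: PhantomConfig = OVERLAP_COHORT,
                         branch: str = "type4") -> ImbalanceStudyResult:
    """|Sen - Spec| of a case-weighted vs a flat-weighted model."""
    records = simulate_cohort(cohort)
    train, valid, test = _first_fold(records, seed=cohort.seed)
    config = TrainConfig(input_size=STUDY_TRAIN.input_size,
                         max_epochs=STUDY_TRAIN.max_epochs, seed=seed)
    test_ds = build_dataset(test, (branch,), config.input_size)
    out = {}
    for name, weights in (("weighted", None),
                          ("unweighted", ClassWeights(1, 1, 0.5, 0.5))):
        enc, _ = train_stage1(branch, EncoderConfig(), train, valid, config,
                              weights=weights)
        scores = predict_scores(make_forward({branch: enc}, None, "ffm_v2"),
                                test_ds)
        report = evaluate_scores(scores, test_ds.labels)
        out[name] = report
    return ImbalanceStudyResult(
        weighted_gap=abs(out["weighted"].sen - out["weighted"].spec),
        unweighted_gap=abs(out["unweighted"].sen - out["unweighted"].spec),
        weighted_auc=out["weighted"].auc,
        unweighted_auc=out["unweighted"].auc,
        n_test_images=len(test_ds.labels))
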