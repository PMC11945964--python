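"""Metrics, case-level splits and four-fold cross-validation.

Malignant is the positive class.  Seven metrics are reported: accuracy,
F1-score, AUC, positive/negative predictive value, sensitivity and
specificity.  Threshold-dependent metrics use 0.5 on the malignancy
probability; AUC is threshold-free (Mann-Whitney convention, ties counted
one half) and is the primary metric.  Undefined ratios (for example PPV
with no positive predictions) surface as NaN with a warning, never as a
silent zero, so cross-fold means are not corrupted.

Splitting is always at the *case* level — no patient contributes images to
more than one of train/validation/test — while metrics are computed at the
image level.  Cross-validation stratifies cases by label into four test
folds; within each fold the remaining cases are split so validation holds
about one third of the non-test cases per class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import DataError
from .phantom import CaseRecord, LABELS


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion table; malignant = positive."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    acc: float
    f1: float
    auc: float
    ppv: float
    npv: float
    sen: float
    spec: float
    counts: ConfusionCounts | None = None
    roc: list[tuple[float, float]] | None = None

    METRIC_NAMES = ("acc", "f1", "auc", "ppv", "npv", "sen", "spec")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.METRIC_NAMES}


def confusion_from_scores(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Threshold malignancy probabilities: predict malignant iff score >= t."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(
            f"scores and labels disagree in length: {scores.shape} vs {labels.shape}"
        )
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)), FP=int(np.sum(pred & ~pos)),
        TN=int(np.sum(~pred & ~pos)), FN=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, F1, PPV, NPV, sensitivity and specificity from counts."""
    if counts.total < 1:
        raise ValueError("confusion table is empty")
    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    acc = (tp + tn) / counts.total
    ppv = _ratio(tp, tp + fp, "PPV")
    npv = _ratio(tn, tn + fn, "NPV")
    sen = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    if np.isnan(ppv) or np.isnan(sen) or (ppv + sen) == 0:
        warnings.warn("F1 undefined; reporting NaN", RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * ppv * sen / (ppv + sen)
    return MetricsReport(acc=acc, f1=f1, auc=float("nan"), ppv=ppv, npv=npv,
                         sen=sen, spec=spec, counts=counts)


def compute_auc(scores, labels) -> tuple[float, list[tuple[float, float]]]:
    """AUC (trapezoidal area = Mann-Whitney with half-ties) plus ROC points."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC requires both classes to be present")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return float(_trapezoid_auc(fpr, tpr)), list(zip(fpr.tolist(), tpr.tolist()))


def evaluate_scores(scores, labels, threshold: float = 0.5) -> MetricsReport:
    """Full seven-metric report from per-image scores."""
    report = compute_metrics(confusion_from_scores(scores, labels, threshold))
    report.auc, report.roc = compute_auc(scores, labels)
    return report


# -- splits -------------------------------------------------------------------

@dataclass
class Fold:
    train: list[str]
    valid: list[str]
    test: list[str]


@dataclass
class FoldPlan:
    n_folds: int
    folds: list[Fold] = field(default_factory=list)


def make_fold_plan(cases: list[CaseRecord], n_folds: int = 4,
                   seed: int = 0) -> FoldPlan:
    """Stratified case-level folds; valid holds ~1/3 of non-test cases."""
    ids = np.array([c.case_id for c in cases])
    labels = np.array([c.label_index for c in cases])
    for lab, name in enumerate(LABELS):
        if int(np.sum(labels == lab)) < n_folds:
            raise DataError(
                f"need at least {n_folds} {name} cases for {n_folds}-fold "
                f"cross-validation, have {int(np.sum(labels == lab))}"
            )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 13]))
    plan = FoldPlan(n_folds=n_folds)
    for rest_idx, test_idx in splitter.split(ids, labels):
        train: list[str] = []
        valid: list[str] = []
        for lab in range(len(LABELS)):
            pool = [i for i in rest_idx if labels[i] == lab]
            pool = list(rng.permutation(pool))
            n_valid = max(1, int(round(len(pool) / 3)))
            if n_valid >= len(pool):
                n_valid = len(pool) - 1
            valid += [ids[i] for i in pool[:n_valid]]
            train += [ids[i] for i in pool[n_valid:]]
        plan.folds.append(Fold(train=sorted(train), valid=sorted(valid),
                               test=sorted(ids[i] for i in test_idx)))
    return plan


def sample_images_per_case(case: CaseRecord | int, n_images: int) -> list[int]:
    """Evenly spaced frame indices: floor(i * n_frames / n_images).

    Accepts a case record or a raw frame count; if the case has fewer
    frames than requested, every frame index is returned.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    n_frames = case if isinstance(case, int) else len(case.frame_paths)
    if n_images >= n_frames:
        return list(range(n_frames))
    return [int(np.floor(i * n_frames / n_images)) for i in range(n_images)]


def mean_report(reports: list[MetricsReport]) -> dict[str, float]:
    """Unweighted arithmetic mean of each metric across folds."""
    return {name: float(np.mean([getattr(r, name) for r in reports]))
            for name in MetricsReport.METRIC_NAMES}


def cross_validate(spec, cohort: list[CaseRecord], n_folds: int = 4,
                   seed: int = 0) -> tuple[list[MetricsReport], dict[str, float]]:
    """Run the two-stage pipeline per fold and average the test metrics.

    ``spec`` is a :class:`m3net.pipeline.ExperimentSpec` describing the
    branches, encoder, fusion variant and training hyperparameters.
    """
    from .pipeline import run_experiment  # runtime import: pipeline uses us too

    plan = make_fold_plan(cohort, n_folds=n_folds, seed=seed)
    by_id = {c.case_id: c for c in cohort}
    reports = []
    for k, fold in enumerate(plan.folds):
        result = run_experiment(
            spec,
            train_records=[by_id[i] for i in fold.train],
            valid_records=[by_id[i] for i in fold.valid],
            test_records=[by_id[i] for i in fold.test],
            seed_offset=k,
        )
        reports.append(result.report)
    return reports, mean_report(reports)
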