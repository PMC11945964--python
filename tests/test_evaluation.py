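"""Confusion counts, the seven metrics, AUC, and case-level fold plans."""

import numpy as np
import pytest

from m3net.errors import DataError
from m3net.evaluation import (ConfusionCounts, compute_auc, compute_metrics,
                              confusion_from_scores, make_fold_plan,
                              mean_report, sample_images_per_case)
from m3net.phantom import PhantomConfig, simulate_cohort


def pair_count_auc(scores, labels):
    """O(n^2) Mann-Whitney oracle: wins + half-ties over pos/neg pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def metrics_oracle(tp, fp, tn, fn):
    """Direct transcription of the metric definitions."""
    out = {}
    out["acc"] = (tp + tn) / (tp + tn + fp + fn)
    out["ppv"] = tp / (tp + fp) if tp + fp else np.nan
    out["npv"] = tn / (tn + fn) if tn + fn else np.nan
    out["sen"] = tp / (tp + fn) if tp + fn else np.nan
    out["spec"] = tn / (tn + fp) if tn + fp else np.nan
    p, r = out["ppv"], out["sen"]
    out["f1"] = 2 * p * r / (p + r) if np.isfinite(p) and np.isfinite(r) \
        and p + r else np.nan
    return out


class TestConfusion:
    def test_all_positive_scores(self):
        c = confusion_from_scores(np.ones(5), np.ones(5, dtype=int))
        assert (c.TP, c.FP, c.TN, c.FN) == (5, 0, 0, 0)

    def test_zero_threshold_predicts_everything_positive(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        c = confusion_from_scores(scores, labels, threshold=0.0)
        assert c.FN == 0 and c.TN == 0

    def test_four_sample_example(self):
        c = confusion_from_scores([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0], 0.5)
        assert (c.TP, c.FN, c.FP, c.TN) == (1, 1, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_from_scores([0.5], [1, 0])


class TestMetrics:
    def test_worked_example(self):
        r = compute_metrics(ConfusionCounts(TP=9, FN=1, TN=8, FP=2))
        assert r.acc == pytest.approx(0.85)
        assert r.sen == pytest.approx(0.90)
        assert r.spec == pytest.approx(0.80)
        assert r.ppv == pytest.approx(9 / 11)
        assert r.npv == pytest.approx(8 / 9)
        assert r.f1 == pytest.approx(2 * (9 / 11) * 0.9 / (9 / 11 + 0.9))

    def test_perfect_classifier(self):
        r = compute_metrics(ConfusionCounts(TP=4, FN=0, TN=6, FP=0))
        for name in ("acc", "f1", "ppv", "npv", "sen", "spec"):
            assert getattr(r, name) == 1.0

    def test_degenerate_denominators_give_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="PPV"):
            r = compute_metrics(ConfusionCounts(TP=0, FP=0, TN=3, FN=2))
        assert np.isnan(r.ppv)
        assert r.spec == 1.0 and r.npv == pytest.approx(0.6)

    def test_matches_oracle_on_random_tables(self, rng):
        import warnings
        for _ in range(300):
            tp, fp, tn, fn = rng.integers(0, 30, 4)
            if tp + fp + tn + fn == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = compute_metrics(ConfusionCounts(int(tp), int(fp),
                                                    int(tn), int(fn)))
            expected = metrics_oracle(tp, fp, tn, fn)
            for name, val in expected.items():
                got = getattr(r, name)
                assert (np.isnan(val) and np.isnan(got)) or \
                    got == pytest.approx(val, abs=1e-12)


class TestAUC:
    def test_perfect_separation(self):
        auc, roc = compute_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0
        assert roc[0] == (0.0, 0.0) and roc[-1] == (1.0, 1.0)

    def test_worked_four_sample_example(self):
        auc, _ = compute_auc([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        auc, _ = compute_auc([0.4] * 6, [1, 0, 1, 0, 1, 0])
        assert auc == pytest.approx(0.5)

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.random(n), 2)   # induce ties
            labels = rng.integers(0, 2, n)
            if len(set(labels)) < 2:
                continue
            auc, _ = compute_auc(scores, labels)
            assert auc == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_roc_monotone(self, rng):
        scores, labels = rng.random(40), rng.integers(0, 2, 40)
        _, roc = compute_auc(scores, labels)
        fpr = [p[0] for p in roc]
        tpr = [p[1] for p in roc]
        assert all(a <= b for a, b in zip(fpr, fpr[1:]))
        assert all(a <= b for a, b in zip(tpr, tpr[1:]))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auc([0.1, 0.9], [1, 1])


class TestFoldPlan:
    def test_balanced_cohort_fold_sizes(self):
        config = PhantomConfig(n_cases_benign=8, n_cases_malignant=8,
                               frames_per_case=1, seed=3)
        records = simulate_cohort(config)
        plan = make_fold_plan(records, n_folds=4, seed=0)
        for fold in plan.folds:
            test_labels = [r for r in fold.test]
            assert len(fold.test) == 4
            assert sum(i.startswith("b") for i in test_labels) == 2

    def test_folds_partition_cases(self, tiny_cohort):
        _, records = tiny_cohort
        plan = make_fold_plan(records, n_folds=4, seed=1)
        all_test = [cid for fold in plan.folds for cid in fold.test]
        assert sorted(all_test) == sorted(r.case_id for r in records)
        for fold in plan.folds:
            assert not (set(fold.train) | set(fold.valid)) & set(fold.test)
            assert not set(fold.train) & set(fold.valid)

    def test_deterministic_under_seed(self, tiny_cohort):
        _, records = tiny_cohort
        a = make_fold_plan(records, n_folds=4, seed=7)
        b = make_fold_plan(records, n_folds=4, seed=7)
        assert [(f.train, f.valid, f.test) for f in a.folds] == \
            [(f.train, f.valid, f.test) for f in b.folds]

    def test_too_few_cases(self):
        config = PhantomConfig(n_cases_benign=2, n_cases_malignant=8,
                               frames_per_case=1, seed=3)
        with pytest.raises(DataError):
            make_fold_plan(simulate_cohort(config), n_folds=4, seed=0)

    def test_validation_fraction_about_one_third(self):
        config = PhantomConfig(n_cases_benign=13, n_cases_malignant=82,
                               frames_per_case=1, seed=3)
        plan = make_fold_plan(simulate_cohort(config), n_folds=4, seed=0)
        for fold in plan.folds:
            frac = len(fold.valid) / (len(fold.valid) + len(fold.train))
            assert 0.25 <= frac <= 0.42


class TestFrameSampling:
    def test_even_spacing(self):
        assert sample_images_per_case(10, 5) == [0, 2, 4, 6, 8]

    def test_request_exceeding_frames_returns_all(self):
        assert sample_images_per_case(3, 7) == [0, 1, 2]

    def test_single_image_is_first_frame(self):
        assert sample_images_per_case(9, 1) == [0]


def test_mean_report_is_unweighted_mean():
    from m3net.evaluation import MetricsReport
    a = MetricsReport(acc=0.8, f1=0.8, auc=0.9, ppv=0.7, npv=0.9, sen=0.8,
                      spec=0.8)
    b = MetricsReport(acc=0.6, f1=0.6, auc=0.7, ppv=0.5, npv=0.7, sen=0.6,
                      spec=0.6)
    mean = mean_report([a, b])
    assert mean["auc"] == pytest.approx(0.8)
    assert mean["acc"] == pytest.approx(0.7)
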