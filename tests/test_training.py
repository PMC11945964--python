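"""Class weights, weighted loss, augmentation, and the two-stage protocol."""

import hashlib

import numpy as np
import pytest

import m3net._nn as nn
from m3net.encoders import EncoderConfig
from m3net.errors import DataError
from m3net.fusion import FusionConfig
from m3net.training import (ClassWeights, TrainConfig, augment,
                            compute_class_weights, parse_branch,
                            train_stage1, train_stage2,
                            weighted_cross_entropy)


def four_step_weights(n_b, n_m):
    """Literal derivation: normalize counts, invert, renormalize."""
    nb_norm = n_b / (n_b + n_m)
    nm_norm = n_m / (n_b + n_m)
    rb, rm = 1.0 / nb_norm, 1.0 / nm_norm
    return rb / (rb + rm), rm / (rb + rm)


class TestClassWeights:
    def test_training_split_case_counts(self):
        w = compute_class_weights(6, 40)
        assert w.w_b == pytest.approx(40 / 46, abs=1e-12)
        assert w.w_m == pytest.approx(6 / 46, abs=1e-12)

    @pytest.mark.parametrize("n_b,n_m,expected", [
        (5, 5, (0.5, 0.5)),
        (1, 3, (0.75, 0.25)),
    ])
    def test_symmetry_and_small_examples(self, n_b, n_m, expected):
        w = compute_class_weights(n_b, n_m)
        assert (w.w_b, w.w_m) == pytest.approx(expected, abs=1e-12)

    def test_matches_four_step_oracle_and_closed_form(self, rng):
        for _ in range(100):
            n_b = int(rng.integers(1, 500))
            n_m = int(rng.integers(1, 500))
            w = compute_class_weights(n_b, n_m)
            ob, om = four_step_weights(n_b, n_m)
            assert abs(w.w_b - ob) < 1e-12 and abs(w.w_m - om) < 1e-12
            assert abs(w.w_b - n_m / (n_b + n_m)) < 1e-12
            assert abs(w.w_b + w.w_m - 1.0) < 1e-12

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            compute_class_weights(0, 5)


class TestWeightedCrossEntropy:
    def test_uniform_logits_closed_form(self):
        loss = weighted_cross_entropy(np.zeros((1, 2)), [0], (0.5, 0.5))
        assert float(loss.numpy()) == pytest.approx(0.5 * np.log(2), abs=1e-12)

    def test_confident_correct_logits_vanish(self):
        logits = np.array([[30.0, -30.0], [-30.0, 30.0]])
        loss = weighted_cross_entropy(logits, [0, 1], (0.5, 0.5))
        assert float(loss.numpy()) < 1e-10

    def test_zero_weight_class_contributes_nothing(self, rng):
        logits = rng.standard_normal((6, 2))
        labels = np.array([0, 1, 1, 0, 1, 1])
        full = weighted_cross_entropy(logits, labels, (1.0, 0.0))
        benign_only = weighted_cross_entropy(logits[labels == 0],
                                             labels[labels == 0], (1.0, 0.0))
        assert float(full.numpy()) * 6 == pytest.approx(
            float(benign_only.numpy()) * 2, abs=1e-12)

    def test_equal_weights_proportional_to_unweighted(self, rng):
        logits = rng.standard_normal((10, 2))
        labels = rng.integers(0, 2, 10)
        half = weighted_cross_entropy(logits, labels, (0.5, 0.5))
        unit = weighted_cross_entropy(logits, labels, (1.0, 1.0))
        assert float(half.numpy()) == pytest.approx(0.5 * float(unit.numpy()),
                                                    rel=1e-12)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            weighted_cross_entropy(np.zeros((1, 2)), [2], (0.5, 0.5))


class TestAugment:
    def test_noop_configuration_returns_input(self, rng):
        img = rng.random((3, 8, 8))
        out = augment([img], rng, hflip=False, vflip=False, rot90=False,
                      jitter=0.0)
        assert np.array_equal(out[0], img)

    def test_group_receives_identical_geometry(self, rng):
        base = rng.random((3, 8, 8))
        # two identical images must stay identical under one shared draw
        for _ in range(10):
            a, b = augment([base, base.copy()], rng, jitter=0.0)
        assert np.array_equal(a, b)

    def test_geometric_ops_preserve_value_set(self, rng):
        img = rng.random((3, 8, 8))
        out = augment([img], rng, jitter=0.0)[0]
        assert np.array_equal(np.sort(out.ravel()), np.sort(img.ravel()))


def _splits(cohort):
    _, records = cohort
    benign = [r for r in records if r.label == "benign"]
    malignant = [r for r in records if r.label == "malignant"]
    train = benign[:4] + malignant[:6]
    valid = benign[4:6] + malignant[6:9]
    return train, valid


class TestStage1:
    def test_history_contract_and_best_checkpoint(self, tiny_cohort,
                                                  quick_train_config,
                                                  tiny_encoder_config):
        train, valid = _splits(tiny_cohort)
        flat = ClassWeights(1, 1, 0.5, 0.5)
        enc, hist = train_stage1("type4", tiny_encoder_config, train, valid,
                                 quick_train_config, weights=flat)
        assert 1 <= len(hist) <= quick_train_config.max_epochs
        if len(hist) < quick_train_config.max_epochs:   # stopped early
            assert len(hist) >= quick_train_config.early_stop_patience + 1
        # returned model is the best-validation-AUC checkpoint
        from m3net.evaluation import compute_auc
        from m3net.training import build_dataset, predict_scores
        ds = build_dataset(valid, ("type4",), quick_train_config.input_size)
        enc.eval()
        scores = predict_scores(lambda b: enc(nn.Tensor(b[0])), ds)
        auc, _ = compute_auc(scores, ds.labels)
        assert auc == pytest.approx(max(h["valid_auc"] for h in hist), abs=1e-9)

    def test_reproducible_under_seed(self, tiny_cohort, quick_train_config,
                                     tiny_encoder_config):
        train, valid = _splits(tiny_cohort)
        _, h1 = train_stage1("type4", tiny_encoder_config, train, valid,
                             quick_train_config)
        _, h2 = train_stage1("type4", tiny_encoder_config, train, valid,
                             quick_train_config)
        assert h1 == h2

    def test_empty_split_rejected(self, tiny_cohort, quick_train_config,
                                  tiny_encoder_config):
        train, _ = _splits(tiny_cohort)
        with pytest.raises(DataError):
            train_stage1("type4", tiny_encoder_config, train, [],
                         quick_train_config)

    def test_overlapping_splits_rejected(self, tiny_cohort, quick_train_config,
                                         tiny_encoder_config):
        train, _ = _splits(tiny_cohort)
        with pytest.raises(DataError, match="overlap"):
            train_stage1("type4", tiny_encoder_config, train, train,
                         quick_train_config)


def _param_hash(module):
    digest = hashlib.sha256()
    for name, value in sorted(module.state_dict().items()):
        digest.update(name.encode())
        digest.update(np.ascontiguousarray(value).tobytes())
    return digest.hexdigest()


class TestStage2:
    def test_encoders_bit_identical_after_training(self, tiny_cohort,
                                                   quick_train_config,
                                                   tiny_encoder_config):
        train, valid = _splits(tiny_cohort)
        encoders = {}
        for branch in ("type4", "polar3"):
            enc, _ = train_stage1(branch, tiny_encoder_config, train, valid,
                                  quick_train_config)
            encoders[branch] = enc
        hashes = {b: _param_hash(e) for b, e in encoders.items()}
        cfg = FusionConfig(variant="ffm_v2", channel_counts=(32, 32))
        head, hist = train_stage2(encoders, cfg, train, valid,
                                  quick_train_config)
        assert {b: _param_hash(e) for b, e in encoders.items()} == hashes
        assert len(hist) >= 1

    def test_frozen_fusion_gives_constant_loss(self, tiny_cohort,
                                               quick_train_config,
                                               tiny_encoder_config):
        train, valid = _splits(tiny_cohort)
        enc, _ = train_stage1("type4", tiny_encoder_config, train, valid,
                              quick_train_config)
        cfg = FusionConfig(variant="ffm_v2", channel_counts=(32, 32))
        from m3net.fusion import FusionHead
        head = FusionHead(cfg, seed=0)
        head.eval()
        for p in head.parameters():
            p.requires_grad = False
        head, hist = train_stage2({"type4": enc, "polar3": enc}, cfg, train,
                                  valid, quick_train_config, head=head)
        assert len({round(h["valid_loss"], 12) for h in hist}) == 1
        assert len({round(h["train_loss"], 12) for h in hist}) == 1


def test_branch_name_parsing():
    assert parse_branch("type4")[0] == "crop"
    assert parse_branch("polar3")[0] == "polar"
    kind, spec = parse_branch("PMS 2-3-4")
    assert kind == "multiscale" and spec.polar and spec.source_types == (2, 3, 4)
    with pytest.raises(Exception):
        parse_branch("type9")
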