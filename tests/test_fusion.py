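"""Fusion algebra: CBAM gating, self-attention, the three variants."""

import numpy as np
import pytest

import m3net._nn as nn
from m3net.errors import ShapeError
from m3net.fusion import (CBAM, Classifier, FFMv1, FFMv2, FFMv3, FusionConfig,
                          FusionHead, MultiHeadSelfAttention, align_branches,
                          default_n_heads, fused_width, map_to_tokens)


def zero_out_projection(mhsa: MultiHeadSelfAttention):
    mhsa.out_proj.weight.data[...] = 0.0
    mhsa.out_proj.bias.data[...] = 0.0


@pytest.fixture
def maps(rng):
    return [nn.Tensor(rng.standard_normal((2, c, 4, 4))) for c in (8, 16, 8)]


class TestCBAM:
    def test_shape_preserved_and_attenuating(self, rng):
        cbam = CBAM(8, rng=rng)
        x = nn.Tensor(rng.standard_normal((3, 8, 5, 5)))
        out = cbam(x)
        assert out.shape == x.shape
        assert np.all(np.abs(out.numpy()) <= np.abs(x.numpy()) + 1e-12)

    def test_zero_input_gives_zero_output(self, rng):
        cbam = CBAM(4, rng=rng)
        out = cbam(nn.Tensor(np.zeros((1, 4, 3, 3))))
        assert np.array_equal(out.numpy(), np.zeros((1, 4, 3, 3)))

    def test_rejects_bad_rank(self, rng):
        with pytest.raises(ShapeError):
            CBAM(4, rng=rng)(nn.Tensor(np.zeros((4, 4))))


class TestMHSA:
    def test_attention_rows_sum_to_one(self, rng):
        mhsa = MultiHeadSelfAttention(12, 4, rng=rng)
        x = nn.Tensor(rng.standard_normal((2, 9, 12)))
        _, attn = mhsa.attention(x)
        assert np.allclose(attn.numpy().sum(axis=-1), 1.0, atol=1e-6)

    def test_single_token_attention_is_identity_weight(self, rng):
        mhsa = MultiHeadSelfAttention(8, 2, rng=rng)
        x = nn.Tensor(rng.standard_normal((1, 1, 8)))
        out, attn = mhsa.attention(x)
        assert np.allclose(attn.numpy(), 1.0)
        expected = mhsa.out_proj(mhsa.v_proj(x)).numpy()
        assert np.allclose(out.numpy(), expected, atol=1e-10)

    def test_permutation_equivariance(self, rng):
        """No positional encoding: permuting tokens permutes the output."""
        mhsa = MultiHeadSelfAttention(8, 2, rng=rng)
        x = rng.standard_normal((1, 4, 8))
        perm = np.array([2, 0, 3, 1])
        out = mhsa(nn.Tensor(x)).numpy()
        out_perm = mhsa(nn.Tensor(x[:, perm])).numpy()
        assert np.allclose(out_perm[:, np.argsort(perm)], out, atol=1e-10)

    def test_divisibility_enforced(self, rng):
        from m3net.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            MultiHeadSelfAttention(10, 4, rng=rng)

    def test_default_heads(self):
        assert default_n_heads(64) == 8
        assert default_n_heads(12) == 4
        assert default_n_heads(7) == 1


class TestFFMv1:
    def test_zeroed_attention_projection_gives_zero(self, maps):
        cfg = FusionConfig(variant="ffm_v1", channel_counts=(8, 16, 8))
        ffm = FFMv1(cfg, rng=np.random.default_rng(0))
        zero_out_projection(ffm.mhsa)
        out = ffm(maps).numpy()
        assert np.allclose(out, 0.0)

    def test_channel_count_is_sum(self, maps):
        cfg = FusionConfig(variant="ffm_v1", channel_counts=(8, 16, 8))
        out = FFMv1(cfg, rng=np.random.default_rng(0))(maps)
        assert out.shape == (2, 32, 4, 4)

    def test_residual_ablation_changes_output(self, maps):
        cfg = FusionConfig(variant="ffm_v1", channel_counts=(8, 16, 8))
        rng_a, rng_b = np.random.default_rng(3), np.random.default_rng(3)
        with_res = FFMv1(cfg, rng=rng_a, use_residual=True)(maps).numpy()
        without = FFMv1(cfg, rng=rng_b, use_residual=False)(maps).numpy()
        assert not np.allclose(with_res, without)

    def test_spatial_mismatch_names_branches(self, rng):
        cfg = FusionConfig(variant="ffm_v1", channel_counts=(8, 8))
        bad = [nn.Tensor(rng.standard_normal((1, 8, 4, 4))),
               nn.Tensor(rng.standard_normal((1, 8, 2, 2)))]
        with pytest.raises(ShapeError, match="branch"):
            FFMv1(cfg, rng=np.random.default_rng(0))(bad)


class TestFFMv2:
    def test_zeroed_projection_gives_identity(self, maps):
        cfg = FusionConfig(variant="ffm_v2", channel_counts=(8, 16, 8))
        ffm = FFMv2(cfg, rng=np.random.default_rng(0))
        zero_out_projection(ffm.mhsa)
        out = ffm(maps).numpy()
        expected = np.concatenate([m.numpy() for m in maps], axis=1)
        assert np.allclose(out, expected, atol=1e-12)

    def test_two_branch_call(self, rng):
        cfg = FusionConfig(variant="ffm_v2", channel_counts=(8, 8))
        ffm = FFMv2(cfg, rng=np.random.default_rng(0))
        x = [nn.Tensor(rng.standard_normal((2, 8, 3, 3))) for _ in range(2)]
        a = ffm(x).numpy()
        b = ffm(x).numpy()
        assert a.shape == (2, 16, 3, 3)
        assert np.array_equal(a, b)


class TestFFMv3:
    def test_output_width(self, maps, rng):
        cfg = FusionConfig(variant="ffm_v3", channel_counts=(8, 16, 8), fc_width=6)
        ffm = FFMv3(cfg, rng=np.random.default_rng(0))
        vecs = [nn.Tensor(rng.standard_normal((2, 6))) for _ in range(3)]
        out = ffm(maps, vecs)
        assert out.shape == (2, 32 + 3 * 6)
        assert fused_width(cfg) == 32 + 3 * 6

    def test_zeroed_projections_reduce_to_pool_and_flatten(self, maps, rng):
        cfg = FusionConfig(variant="ffm_v3", channel_counts=(8, 16, 8), fc_width=6)
        ffm = FFMv3(cfg, rng=np.random.default_rng(0))
        zero_out_projection(ffm.map_mhsa)
        zero_out_projection(ffm.vec_mhsa)
        vecs = [nn.Tensor(rng.standard_normal((2, 6))) for _ in range(3)]
        out = ffm(maps, vecs).numpy()
        xm = np.concatenate([m.numpy() for m in maps], axis=1)
        pooled = xm.mean(axis=(2, 3))
        flat = np.concatenate([v.numpy() for v in vecs], axis=1)
        assert np.allclose(out, np.concatenate([pooled, flat], axis=1), atol=1e-12)

    def test_vector_path_ablation_matches_v2_plus_pooling(self, maps):
        cfg = FusionConfig(variant="ffm_v3", channel_counts=(8, 16, 8), fc_width=6)
        seed_rng = np.random.default_rng(9)
        ffm3 = FFMv3(cfg, rng=np.random.default_rng(9), use_vector_path=False)
        cfg2 = FusionConfig(variant="ffm_v2", channel_counts=(8, 16, 8))
        ffm2 = FFMv2(cfg2, rng=seed_rng)
        out3 = ffm3(maps).numpy()
        out2 = ffm2(maps).numpy().mean(axis=(2, 3))
        assert np.allclose(out3, out2, atol=1e-10)


class TestClassifierAndAlign:
    def test_logits_shape_and_softmax(self, rng):
        clf = Classifier(16, rng=rng)
        clf.eval()
        x = nn.Tensor(rng.standard_normal((8, 16, 3, 3)))
        logits = clf(x).numpy()
        assert logits.shape == (8, 2)
        p = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_constant_input_gives_identical_logits(self, rng):
        clf = Classifier(4, rng=rng)
        clf.eval()
        x = nn.Tensor(np.tile(rng.standard_normal((1, 4)), (6, 1)))
        logits = clf(x).numpy()
        assert np.allclose(logits, logits[0])

    def test_nonfinite_rejected(self, rng):
        clf = Classifier(4, rng=rng)
        with pytest.raises(FloatingPointError):
            clf(nn.Tensor(np.full((2, 4), np.nan)))

    def test_align_pools_to_smallest_grid(self, rng):
        a = rng.standard_normal((1, 4, 8, 8))
        b = rng.standard_normal((1, 6, 4, 4))
        out = align_branches([a, b])
        assert out[0].shape == (1, 4, 4, 4)
        assert np.array_equal(out[1], b)
        const = np.full((1, 2, 8, 8), 3.5)
        assert np.allclose(align_branches([const, b])[0], 3.5)

    def test_align_rejects_empty(self):
        with pytest.raises(ValueError):
            align_branches([])


def test_gradients_flow_only_into_fusion_when_encoders_frozen(rng):
    """End-to-end: frozen branches receive no gradient, fusion head does."""
    from m3net.encoders import EncoderConfig, build_encoder
    enc = build_encoder(EncoderConfig(), seed=0)
    enc.eval()
    for p in enc.parameters():
        p.requires_grad = False
    head = FusionHead(FusionConfig(variant="ffm_v2", channel_counts=(32, 32)),
                      seed=1)
    x = rng.random((2, 3, 16, 16))
    with nn.no_grad():
        fmap = enc.forward_features(nn.Tensor(x))
    logits = head([fmap, fmap])
    logits.sum().backward()
    assert all(p.grad is None for p in enc.parameters())
    grads = [p.grad for p in head.parameters()]
    assert any(g is not None and np.abs(g).sum() > 0 for g in grads)
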