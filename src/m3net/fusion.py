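"""Attention-based feature fusion modules and the classifier head.

Three fusion variants combine the per-branch encoder features:

* **FFM-v1** — each branch map ``Fk`` passes through a CBAM attention layer
  with an additive residual (``Fk' = Fk + CBAM(Fk)``); the gated maps are
  concatenated along channels and refined by multi-head self-attention
  (MHSA) over spatial positions: ``F'' = MHSA(concat(F1', F2', F3'))``.
* **FFM-v2** — the simplest: concatenate first, then MHSA with an additive
  residual: ``F'' = X + MHSA(X)`` with ``X = concat(F1, F2, F3)``.
* **FFM-v3** — FFM-v2's map path plus a parallel fusion of the encoders'
  head FC features: the per-branch width-``fc_width`` vectors form a short
  token sequence fused by MHSA with a residual; the pooled map path and the
  flattened vector path are concatenated into one vector for the
  classifier.

MHSA over a feature map treats the ``h*w`` spatial positions as tokens with
the channel axis as the embedding (no positional encoding), so parameter
count is independent of the spatial extent.  The classifier is adaptive
average pooling -> flatten -> batch-norm -> fully connected (2 logits);
vector-shaped input skips the pooling.

All variants accept 2, 3 or 4 branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn as nn
from .errors import ConfigurationError, ShapeError


def default_n_heads(embed_dim: int) -> int:
    """Largest of {8, 4, 2, 1} dividing the embedding dimension."""
    for h in (8, 4, 2, 1):
        if embed_dim % h == 0:
            return h
    return 1


@dataclass(frozen=True)
class FusionConfig:
    """Which variant to build and the branch geometry it must accept."""

    variant: str = "ffm_v2"
    channel_counts: tuple[int, ...] = (32, 32)
    spatial_size: tuple[int, int] = (4, 4)
    n_heads: int | None = None
    fc_width: int = 32

    def __post_init__(self):
        if self.variant not in ("ffm_v1", "ffm_v2", "ffm_v3"):
            raise ConfigurationError(f"unknown fusion variant {self.variant!r}")
        if not 2 <= len(self.channel_counts) <= 4:
            raise ConfigurationError("fusion requires between 2 and 4 branches")
        total = sum(self.channel_counts)
        heads = self.n_heads if self.n_heads is not None else default_n_heads(total)
        if total % heads != 0:
            raise ConfigurationError(
                f"total channel count {total} not divisible by n_heads={heads}"
            )

    @property
    def total_channels(self) -> int:
        return sum(self.channel_counts)

    @property
    def heads(self) -> int:
        return self.n_heads if self.n_heads is not None else default_n_heads(
            self.total_channels)


class CBAM(nn.Module):
    """Convolutional Block Attention Module: channel then spatial gating.

    Channel attention: a shared 2-layer MLP applied to the global-average
    and global-max channel descriptors, summed and sigmoid-gated.  Spatial
    attention: a 7x7 convolution over the stacked channel-mean and
    channel-max maps, sigmoid-gated.  Both gates lie in (0, 1), so the
    output never exceeds the input in magnitude.
    """

    def __init__(self, channels: int, reduction: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.mlp = nn.Sequential(nn.Linear(channels, hidden, rng=rng), nn.ReLU(),
                                 nn.Linear(hidden, channels, rng=rng))
        self.spatial_conv = nn.Conv2d(2, 1, 7, padding=3, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
            squeeze = True
        elif x.ndim == 4:
            squeeze = False
        else:
            raise ShapeError(f"CBAM expects a CHW or NCHW input, got shape {x.shape}")
        avg = x.mean(axis=(2, 3))
        mx = x.max(axis=3).max(axis=2)
        gate_c = (self.mlp(avg) + self.mlp(mx)).sigmoid()
        x = x * gate_c.reshape(x.shape[0], x.shape[1], 1, 1)
        smean = x.mean(axis=1, keepdims=True)
        smax = x.max(axis=1, keepdims=True)
        gate_s = self.spatial_conv(nn.concat([smean, smax], axis=1)).sigmoid()
        out = x * gate_s
        return out.reshape(*out.shape[1:]) if squeeze else out


class MultiHeadSelfAttention(nn.Module):
    """Standard scaled dot-product multi-head self-attention over tokens."""

    def __init__(self, embed_dim: int, n_heads: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if embed_dim % n_heads != 0:
            raise ConfigurationError(
                f"embed_dim {embed_dim} not divisible by n_heads {n_heads}"
            )
        self.embed_dim = embed_dim
        self.n_heads = n_heads
        self.q_proj = nn.Linear(embed_dim, embed_dim, rng=rng)
        self.k_proj = nn.Linear(embed_dim, embed_dim, rng=rng)
        self.v_proj = nn.Linear(embed_dim, embed_dim, rng=rng)
        self.out_proj = nn.Linear(embed_dim, embed_dim, rng=rng)

    def _split_heads(self, x: nn.Tensor) -> nn.Tensor:
        B, T, _ = x.shape
        dh = self.embed_dim // self.n_heads
        return x.reshape(B, T, self.n_heads, dh).transpose(0, 2, 1, 3)

    def attention(self, tokens: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        """Return (output tokens, attention weights (B, heads, T, T))."""
        if tokens.ndim != 3:
            raise ShapeError(f"expected (batch, tokens, embed), got {tokens.shape}")
        if tokens.shape[2] != self.embed_dim:
            raise ShapeError(
                f"embedding width {tokens.shape[2]} != configured {self.embed_dim}"
            )
        q = self._split_heads(self.q_proj(tokens))
        k = self._split_heads(self.k_proj(tokens))
        v = self._split_heads(self.v_proj(tokens))
        dh = self.embed_dim // self.n_heads
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
        attn = nn.softmax(scores, axis=-1)
        out = attn @ v
        B, _, T, _ = out.shape
        out = out.transpose(0, 2, 1, 3).reshape(B, T, self.embed_dim)
        return self.out_proj(out), attn

    def forward(self, tokens: nn.Tensor) -> nn.Tensor:
        return self.attention(tokens)[0]


def map_to_tokens(fmap: nn.Tensor) -> nn.Tensor:
    """(B, C, h, w) -> (B, h*w, C): spatial positions as tokens."""
    B, C, h, w = fmap.shape
    return fmap.reshape(B, C, h * w).transpose(0, 2, 1)


def tokens_to_map(tokens: nn.Tensor, spatial: tuple[int, int]) -> nn.Tensor:
    B, T, C = tokens.shape
    return tokens.transpose(0, 2, 1).reshape(B, C, *spatial)


def align_branches(maps: list) -> list:
    """Adaptively average-pool every map onto the smallest spatial grid."""
    if not maps:
        raise ValueError("align_branches requires at least one feature map")
    tensors = [m if isinstance(m, nn.Tensor) else nn.Tensor(m) for m in maps]
    hs = [t.shape[-2] for t in tensors]
    ws = [t.shape[-1] for t in tensors]
    target = (min(hs), min(ws))
    out = []
    for t, m in zip(tensors, maps):
        if t.shape[-2:] == target:
            aligned = t
        else:
            aligned = nn.adaptive_avg_pool2d(t, target)
        out.append(aligned if isinstance(m, nn.Tensor) else aligned.numpy())
    return out


def _check_branches(maps: list[nn.Tensor]) -> None:
    sizes = {tuple(m.shape[-2:]) for m in maps}
    if len(sizes) != 1:
        raise ShapeError(
            "branch feature maps disagree in spatial size: "
            + ", ".join(f"branch {i}: {tuple(m.shape[-2:])}" for i, m in enumerate(maps))
        )


class FFMv1(nn.Module):
    """Per-branch CBAM with residual, then MHSA over the concatenation."""

    def __init__(self, config: FusionConfig, rng=None, use_residual: bool = True):
        super().__init__()
        self.config = config
        self.use_residual = use_residual
        self.cbam = [CBAM(c, rng=rng) for c in config.channel_counts]
        self.mhsa = MultiHeadSelfAttention(config.total_channels, config.heads, rng=rng)

    def forward(self, maps: list[nn.Tensor]) -> nn.Tensor:
        _check_branches(maps)
        gated = []
        for fmap, cbam in zip(maps, self.cbam):
            g = cbam(fmap)
            gated.append(fmap + g if self.use_residual else g)
        x = nn.concat(gated, axis=1)
        tokens = self.mhsa(map_to_tokens(x))
        return tokens_to_map(tokens, tuple(x.shape[-2:]))


class FFMv2(nn.Module):
    """Concatenate, then MHSA with an additive residual."""

    def __init__(self, config: FusionConfig, rng=None):
        super().__init__()
        self.config = config
        self.mhsa = MultiHeadSelfAttention(config.total_channels, config.heads, rng=rng)

    def forward(self, maps: list[nn.Tensor]) -> nn.Tensor:
        _check_branches(maps)
        x = nn.concat(maps, axis=1)
        tokens = map_to_tokens(x)
        out = tokens + self.mhsa(tokens)
        return tokens_to_map(out, tuple(x.shape[-2:]))


class FFMv3(nn.Module):
    """FFM-v2's map path plus a parallel MHSA fusion of head FC features.

    The two attention paths have independent parameters.  The map path is
    globally average-pooled before the final concatenation so the
    classifier receives a fixed-width vector:
    ``F'' = concat(pool(Xm + MHSA(Xm)), flatten(Xv + MHSA(Xv)))``.
    """

    def __init__(self, config: FusionConfig, rng=None, use_vector_path: bool = True):
        super().__init__()
        self.config = config
        self.use_vector_path = use_vector_path
        self.map_mhsa = MultiHeadSelfAttention(config.total_channels, config.heads,
                                               rng=rng)
        self.vec_mhsa = MultiHeadSelfAttention(
            config.fc_width, default_n_heads(config.fc_width)
            if config.fc_width % config.heads else config.heads, rng=rng)

    def forward(self, maps: list[nn.Tensor],
                fc_vectors: list[nn.Tensor] | None = None) -> nn.Tensor:
        _check_branches(maps)
        x = nn.concat(maps, axis=1)
        tokens = map_to_tokens(x)
        fused_map = tokens + self.map_mhsa(tokens)
        pooled = fused_map.mean(axis=1)          # (B, C_total): global average
        if not self.use_vector_path:
            return pooled
        if fc_vectors is None:
            raise ShapeError("ffm_v3 requires per-branch FC feature vectors")
        widths = {v.shape[-1] for v in fc_vectors}
        if widths != {self.config.fc_width}:
            raise ShapeError(
                f"FC feature widths {sorted(widths)} != configured "
                f"{self.config.fc_width}"
            )
        vec_tokens = nn.concat([v.reshape(v.shape[0], 1, v.shape[1])
                                for v in fc_vectors], axis=1)
        fused_vec = vec_tokens + self.vec_mhsa(vec_tokens)
        flat = fused_vec.reshape(fused_vec.shape[0], -1)
        return nn.concat([pooled, flat], axis=1)


class Classifier(nn.Module):
    """Adaptive average pool -> flatten -> batch-norm -> FC (2 logits).

    Vector-shaped input (the FFM-v3 output) skips the pooling stage.
    """

    def __init__(self, in_features: int, rng=None):
        super().__init__()
        self.bn = nn.BatchNorm1d(in_features)
        self.fc = nn.Linear(in_features, 2, rng=rng)

    def forward(self, fused: nn.Tensor) -> nn.Tensor:
        if not np.all(np.isfinite(fused.numpy())):
            raise FloatingPointError("fused features contain non-finite values")
        if fused.ndim == 4:
            fused = nn.adaptive_avg_pool2d(fused, (1, 1)).reshape(fused.shape[0], -1)
        elif fused.ndim != 2:
            raise ShapeError(f"classifier expects NCHW or NxD input, got {fused.shape}")
        return self.fc(self.bn(fused))


def build_fusion(config: FusionConfig, seed: int | None = None) -> nn.Module:
    rng = np.random.default_rng(seed) if seed is not None else None
    if config.variant == "ffm_v1":
        return FFMv1(config, rng=rng)
    if config.variant == "ffm_v2":
        return FFMv2(config, rng=rng)
    return FFMv3(config, rng=rng)


def fused_width(config: FusionConfig) -> int:
    """Width of the classifier input produced by the configured variant."""
    if config.variant == "ffm_v3":
        return config.total_channels + len(config.channel_counts) * config.fc_width
    return config.total_channels


class FusionHead(nn.Module):
    """Fusion module plus classifier: branch features in, logits out."""

    def __init__(self, config: FusionConfig, seed: int | None = None):
        super().__init__()
        rng = np.random.default_rng(seed) if seed is not None else None
        self.config = config
        self.fusion = build_fusion(config, seed=seed)
        self.classifier = Classifier(fused_width(config), rng=rng)

    def forward(self, maps: list[nn.Tensor],
                fc_vectors: list[nn.Tensor] | None = None) -> nn.Tensor:
        maps = [m if isinstance(m, nn.Tensor) else nn.Tensor(m) for m in maps]
        if fc_vectors is not None:
            fc_vectors = [v if isinstance(v, nn.Tensor) else nn.Tensor(v)
                          for v in fc_vectors]
        if self.config.variant == "ffm_v3":
            fused = self.fusion(maps, fc_vectors)
        else:
            fused = self.fusion(maps)
        return self.classifier(fused)
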