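"""Per-branch CNN encoders with a replaceable classifier head.

Each branch of the fusion framework is a CNN trained on one EBUS image
variant.  The backbone's own classifier is replaced by a three-layer head

    FC(d -> h1) -> BatchNorm -> ReLU -> Dropout ->
    FC(h1 -> h2) -> BatchNorm -> ReLU -> Dropout -> FC(h2 -> 2)

whose logits drive stage-1 fine-tuning.  After fine-tuning the encoder is
frozen and used purely for feature extraction: the last convolutional
block's activation map (``extract_feature_map``) feeds the fusion modules,
and the width-``h2`` activation after the second head block
(``extract_fc_feature``) supplies the global "FC features" used by the
third fusion variant.

Backbones here are small scratch CNNs sized so the full two-stage pipeline
trains on a CPU in minutes; the registry is open — any module emitting an
NCHW feature map can be added via :func:`register_backbone`.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn as nn
from .errors import ConfigurationError, ShapeError

N_CLASSES = 2


@dataclass(frozen=True)
class EncoderConfig:
    backbone_name: str = "tiny_cnn"
    pretrained: bool = False
    head_dims: tuple[int, int, int, int] | None = None
    dropout_p: float = 0.5
    feature_stage: str = "last_conv"

    def validate(self) -> None:
        if self.backbone_name not in _REGISTRY:
            raise ConfigurationError(
                f"unknown backbone {self.backbone_name!r}; "
                f"available: {sorted(_REGISTRY)}"
            )
        if self.pretrained:
            raise ConfigurationError(
                f"no pretrained weights are bundled for {self.backbone_name!r}; "
                "set pretrained=False"
            )
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigurationError("dropout_p must lie in [0, 1)")
        if self.feature_stage not in ("last_conv", "penultimate_fc"):
            raise ConfigurationError(
                f"feature_stage must be 'last_conv' or 'penultimate_fc', "
                f"got {self.feature_stage!r}"
            )
        if self.head_dims is not None and self.head_dims[-1] != N_CLASSES:
            raise ConfigurationError(
                f"head output dimension must be {N_CLASSES}, got {self.head_dims[-1]}"
            )


# -- backbone registry --------------------------------------------------------

_REGISTRY: dict[str, dict] = {}


def register_backbone(name: str, builder, feature_channels: int,
                      default_head: tuple[int, int, int, int]) -> None:
    """Register a backbone: ``builder(rng) -> Module`` emitting NCHW maps."""
    _REGISTRY[name] = {
        "builder": builder,
        "feature_channels": feature_channels,
        "default_head": default_head,
    }


def _conv_stage(cin: int, cout: int, rng) -> nn.Sequential:
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, stride=2, padding=1, rng=rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


def _tiny_cnn(rng) -> nn.Sequential:
    # 3 stride-2 stages: spatial size divides by 8, ~6k conv parameters.
    return nn.Sequential(_conv_stage(3, 8, rng), _conv_stage(8, 16, rng),
                         _conv_stage(16, 32, rng))


def _small_cnn(rng) -> nn.Sequential:
    return nn.Sequential(_conv_stage(3, 16, rng), _conv_stage(16, 32, rng),
                         _conv_stage(32, 64, rng), _conv_stage(64, 64, rng))


register_backbone("tiny_cnn", _tiny_cnn, 32, (32, 64, 32, N_CLASSES))
register_backbone("small_cnn", _small_cnn, 64, (64, 128, 64, N_CLASSES))


class Encoder(nn.Module):
    """Backbone + global average pooling + the three-layer classifier head."""

    def __init__(self, config: EncoderConfig, seed: int | None = None):
        super().__init__()
        config.validate()
        entry = _REGISTRY[config.backbone_name]
        rng = np.random.default_rng(seed) if seed is not None else nn.get_rng()
        head_dims = config.head_dims or entry["default_head"]
        if head_dims[0] != entry["feature_channels"]:
            raise ConfigurationError(
                f"head input width {head_dims[0]} does not match the "
                f"{config.backbone_name} feature width {entry['feature_channels']}"
            )
        self.config = config
        self.head_dims = tuple(head_dims)
        self.features = entry["builder"](rng)
        d, h1, h2, out = head_dims
        p = config.dropout_p
        self.head_block1 = nn.Sequential(
            nn.Linear(d, h1, rng=rng), nn.BatchNorm1d(h1), nn.ReLU(), nn.Dropout(p))
        self.head_block2 = nn.Sequential(
            nn.Linear(h1, h2, rng=rng), nn.BatchNorm1d(h2), nn.ReLU(), nn.Dropout(p))
        self.head_out = nn.Linear(h2, out, rng=rng)

    @property
    def feature_channels(self) -> int:
        return self.head_dims[0]

    @property
    def fc_width(self) -> int:
        return self.head_dims[2]

    def forward_features(self, x: nn.Tensor) -> nn.Tensor:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError(f"expected an NCHW RGB batch, got shape {x.shape}")
        return self.features(x)

    def _pool(self, fmap: nn.Tensor) -> nn.Tensor:
        return nn.adaptive_avg_pool2d(fmap, (1, 1)).reshape(fmap.shape[0], -1)

    def forward_fc(self, x: nn.Tensor) -> nn.Tensor:
        """Activation after the second head block (width h2)."""
        return self.head_block2(self.head_block1(self._pool(self.forward_features(x))))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.head_out(self.forward_fc(x))


def build_encoder(config: EncoderConfig, seed: int | None = None) -> Encoder:
    """Construct an encoder; with a seed, initialization is reproducible."""
    return Encoder(config, seed=seed)


def _as_batch(images: np.ndarray | nn.Tensor) -> nn.Tensor:
    if isinstance(images, nn.Tensor):
        return images
    arr = np.asarray(images, dtype=np.float64)
    if arr.ndim != 4:
        raise ShapeError(f"expected an NCHW batch, got shape {arr.shape}")
    return nn.Tensor(arr)


def extract_feature_map(encoder: Encoder, images) -> np.ndarray:
    """Frozen, gradient-free last-conv feature maps (B, C, h, w)."""
    was_training = encoder.training
    encoder.eval()
    try:
        with nn.no_grad():
            out = encoder.forward_features(_as_batch(images)).numpy().copy()
    finally:
        encoder.train(was_training)
    return out


def extract_fc_feature(encoder: Encoder, images) -> np.ndarray:
    """Frozen, gradient-free head features of width h2 (B, h2)."""
    was_training = encoder.training
    encoder.eval()
    try:
        with nn.no_grad():
            out = encoder.forward_fc(_as_batch(images)).numpy().copy()
    finally:
        encoder.train(was_training)
    return out


@dataclass
class FeatureBundle:
    """Per-branch feature maps (and optionally head FC vectors) to fuse."""

    maps: list[np.ndarray]
    fc: list[np.ndarray] | None = None


# -- checkpoints --------------------------------------------------------------

def save_encoder(encoder: Encoder, path: str | Path) -> None:
    """Single-file archive: parameters/buffers plus the config as JSON."""
    payload = {f"param/{k}": v for k, v in encoder.state_dict().items()}
    header = asdict(encoder.config)
    header["head_dims"] = list(encoder.head_dims)
    buf = io.BytesIO()
    np.savez(buf, __config__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **payload)
    Path(path).write_bytes(buf.getvalue())


def load_encoder(path: str | Path) -> Encoder:
    with np.load(Path(path), allow_pickle=False) as archive:
        header = json.loads(bytes(archive["__config__"]).decode())
        header["head_dims"] = tuple(header["head_dims"])
        config = EncoderConfig(**header)
        encoder = Encoder(config, seed=0)
        encoder.load_state_dict({k[len("param/"):]: archive[k]
                                 for k in archive.files if k.startswith("param/")})
    encoder.eval()
    return encoder
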