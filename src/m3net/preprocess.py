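"""Probe-centred cropping and polar unwrapping of radial EBUS frames.

Radial-probe ultrasound produces a circular field centred on the probe, so
two geometric primitives drive all downstream image variants:

* :func:`slbic_crop` — scale-calibrated square crops centred on the probe.
  Four fixed physical fields of view are used: 4 x 4 cm (Type 1), 3 x 3 cm
  (Type 2), 2 x 2 cm (Type 3) and 1 x 1 cm (Type 4).  Calibration
  (pixels per cm) and the probe centre are supplied by the case manifest.
* :func:`polar_transform` — unwrap the circular field onto (radius, angle)
  axes about the probe centre.

Conventions (fixed so results are bit-reproducible): coordinates are
(row, col), 0-based, half-open ranges; crops never resample; polar output
rows index radius increasing outward and columns index angle, sampled at
pixel centres, with angle measured from the +col direction toward +row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, GeometryError, ShapeError

#: Physical crop side (cm) per crop type.
CROP_SIDE_CM = {1: 4.0, 2: 3.0, 3: 2.0, 4: 1.0}


@dataclass(frozen=True)
class CropSpec:
    """One of the four probe-centred crop types."""

    type_id: int

    def __post_init__(self):
        if self.type_id not in CROP_SIDE_CM:
            raise ConfigurationError(
                f"crop type must be one of {sorted(CROP_SIDE_CM)}, got {self.type_id}"
            )

    @property
    def side_cm(self) -> float:
        return CROP_SIDE_CM[self.type_id]


@dataclass(frozen=True)
class PolarSpec:
    """Output grid and sampling rule of the polar transform."""

    n_radius: int = 224
    n_angle: int = 224
    r_max_px: float = 112.0
    interpolation: str = "bilinear"

    def __post_init__(self):
        if self.n_radius <= 0 or self.n_angle <= 0:
            raise ConfigurationError("polar output grid must be positive")
        if self.r_max_px <= 0:
            raise ConfigurationError("r_max_px must be positive")
        if self.interpolation not in ("nearest", "bilinear"):
            raise ConfigurationError(
                f"interpolation must be 'nearest' or 'bilinear', got {self.interpolation!r}"
            )


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


def crop_side_px(spec: CropSpec, pixels_per_cm: float) -> int:
    """Crop side in pixels: round(side_cm * pixels_per_cm), half away from zero."""
    return int(_round_half_up(spec.side_cm * pixels_per_cm))


def slbic_crop(frame: np.ndarray, probe_center_px: tuple[int, int],
               pixels_per_cm: float, spec: CropSpec) -> np.ndarray:
    """Probe-centred square crop of one physical scale, without resampling.

    The crop spans the half-open ranges ``[center - side//2, center - side//2
    + side)`` on both axes; for even sides the probe lands on pixel index
    ``side // 2`` of the crop.
    """
    if frame.ndim not in (2, 3):
        raise ShapeError(f"frame must be 2-D or 3-D, got ndim={frame.ndim}")
    side = crop_side_px(spec, pixels_per_cm)
    r0 = probe_center_px[0] - side // 2
    c0 = probe_center_px[1] - side // 2
    r1, c1 = r0 + side, c0 + side
    h, w = frame.shape[:2]
    overhang = {
        "top": max(0, -r0), "left": max(0, -c0),
        "bottom": max(0, r1 - h), "right": max(0, c1 - w),
    }
    if any(overhang.values()):
        detail = ", ".join(f"{k}={v}px" for k, v in overhang.items() if v)
        raise GeometryError(
            f"Type-{spec.type_id} crop ({side}px) at centre {probe_center_px} "
            f"exceeds the {h}x{w} frame: {detail}"
        )
    return frame[r0:r1, c0:c1].copy()


def polar_transform(image: np.ndarray, probe_center_px: tuple[int, int],
                    spec: PolarSpec) -> np.ndarray:
    """Unwrap a probe-centred image onto a (radius x angle) grid.

    Output pixel (i, j) samples the input at radius
    ``r = (i + 0.5) / n_radius * r_max_px`` and angle
    ``theta = (j + 0.5) / n_angle * 2 pi`` from the probe centre
    (``row = center_row + r sin theta``, ``col = center_col + r cos theta``).
    """
    if image.ndim not in (2, 3):
        raise ShapeError(f"image must be 2-D or 3-D, got ndim={image.ndim}")
    h, w = image.shape[:2]
    pr, pc = probe_center_px
    margin = min(pr, pc, h - 1 - pr, w - 1 - pc)
    if spec.r_max_px > margin + 0.5:
        raise GeometryError(
            f"r_max_px={spec.r_max_px} exceeds the distance {margin} from probe "
            f"centre {probe_center_px} to the nearest edge of the {h}x{w} image"
        )
    i = np.arange(spec.n_radius, dtype=np.float64)
    j = np.arange(spec.n_angle, dtype=np.float64)
    r = (i + 0.5) / spec.n_radius * spec.r_max_px
    theta = (j + 0.5) / spec.n_angle * 2.0 * np.pi
    rows = pr + r[:, None] * np.sin(theta)[None, :]
    cols = pc + r[:, None] * np.cos(theta)[None, :]

    def sample_plane(plane: np.ndarray) -> np.ndarray:
        if spec.interpolation == "nearest":
            ri = np.clip(np.floor(rows + 0.5).astype(np.intp), 0, h - 1)
            ci = np.clip(np.floor(cols + 0.5).astype(np.intp), 0, w - 1)
            return plane[ri, ci]
        out = ndimage.map_coordinates(plane.astype(np.float64), [rows, cols],
                                      order=1, mode="nearest")
        if np.issubdtype(plane.dtype, np.integer):
            return _round_half_up(out).astype(plane.dtype)
        return out.astype(plane.dtype)

    if image.ndim == 2:
        return sample_plane(image)
    return np.stack([sample_plane(image[..., k]) for k in range(image.shape[2])],
                    axis=-1)


#: ITU-R BT.601 luma weights for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """BT.601 luma conversion, rounded half-up to 8-bit."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError(f"expected a 3-channel RGB image, got shape {image.shape}")
    luma = (LUMA_WEIGHTS[0] * image[..., 0].astype(np.float64)
            + LUMA_WEIGHTS[1] * image[..., 1]
            + LUMA_WEIGHTS[2] * image[..., 2])
    return _round_half_up(np.clip(luma, 0, 255)).astype(np.uint8)


def resize_to(image: np.ndarray, size: tuple[int, int],
              interpolation: str = "bilinear") -> np.ndarray:
    """Resize to (h, w); bilinear by default, identity when already that size."""
    h, w = size
    if h <= 0 or w <= 0:
        raise ConfigurationError(f"target size must be positive, got {size}")
    if image.shape[:2] == (h, w):
        return image.copy()
    order = {"nearest": 0, "bilinear": 1}.get(interpolation)
    if order is None:
        raise ConfigurationError(f"unknown interpolation {interpolation!r}")
    out = _sk_resize(image.astype(np.float64), (h, w) + image.shape[2:],
                     order=order, mode="edge", anti_aliasing=False,
                     preserve_range=True)
    if np.issubdtype(image.dtype, np.integer):
        return _round_half_up(np.clip(out, 0, 255)).astype(image.dtype)
    return out.astype(image.dtype)
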