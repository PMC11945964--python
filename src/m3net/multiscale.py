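"""Multi-scale RGB composites of three gray-scale EBUS variants.

A multi-scale image packs three physical scales of the same frame into one
3-channel image: each of three gray-scale crops (Types 1-4, optionally
polar-unwrapped) becomes one RGB channel.  Six named variants exist —
MS 1-2-3, MS 1-2-4, MS 2-3-4 from the plain crops and PMS 1-2-3,
PMS 1-2-4, PMS 2-3-4 from the polar-transformed crops.

Channel order is fixed: R holds the smallest source type id (largest
physical field of view), G the middle, B the largest id.  Any fixed order
is equivalent up to a channel permutation the downstream encoder absorbs;
fixing one makes composites reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ShapeError

_TRIPLES = ((1, 2, 3), (1, 2, 4), (2, 3, 4))


@dataclass(frozen=True)
class MultiScaleSpec:
    """A named composite: which three source types, polar or not."""

    source_types: tuple[int, int, int]
    polar: bool

    def __post_init__(self):
        if tuple(self.source_types) not in _TRIPLES:
            raise ConfigurationError(
                f"source_types must be one of {_TRIPLES}, got {self.source_types}"
            )

    @property
    def name(self) -> str:
        prefix = "PMS" if self.polar else "MS"
        return f"{prefix} {'-'.join(str(t) for t in self.source_types)}"

    @staticmethod
    def from_name(name: str) -> "MultiScaleSpec":
        norm = name.strip().upper().replace("_", " ").replace("-", " ").split()
        if len(norm) == 4 and norm[0] in ("MS", "PMS"):
            try:
                types = tuple(int(t) for t in norm[1:])
            except ValueError:
                types = ()
            if types in _TRIPLES:
                return MultiScaleSpec(source_types=types, polar=norm[0] == "PMS")
        raise ConfigurationError(f"unknown multi-scale spec name {name!r}")


def enumerate_specs() -> list[MultiScaleSpec]:
    """The six composite variants: three plain (MS) and three polar (PMS)."""
    return [MultiScaleSpec(source_types=t, polar=p)
            for p in (False, True) for t in _TRIPLES]


@dataclass(frozen=True)
class MultiScaleImage:
    """A composite plus the spec and frame it came from."""

    pixels: np.ndarray
    spec: MultiScaleSpec
    provenance: tuple[str, int] = ("", 0)


def generate_multiscale(gray_images: dict[int, np.ndarray],
                        spec: MultiScaleSpec,
                        provenance: tuple[str, int] = ("", 0)) -> MultiScaleImage:
    """Merge three single-channel images into one RGB composite.

    ``gray_images`` maps type id to a single-channel image; all three of
    ``spec.source_types`` must be present and share one square size.
    Channels are copied unmodified (R <- smallest type id).
    """
    planes = []
    for t in spec.source_types:
        if t not in gray_images:
            raise KeyError(f"gray image for type {t} missing from input")
        plane = np.asarray(gray_images[t])
        if plane.ndim != 2:
            raise ShapeError(f"type {t}: expected single-channel image, "
                             f"got shape {plane.shape}")
        planes.append(plane)
    shapes = {p.shape for p in planes}
    if len(shapes) != 1:
        raise ShapeError(f"source images disagree in size: {sorted(shapes)}")
    pixels = np.stack(planes, axis=-1)
    return MultiScaleImage(pixels=pixels, spec=spec, provenance=provenance)


def split_channels(composite: MultiScaleImage) -> dict[int, np.ndarray]:
    """Recover the three gray sources from a composite, keyed by type id."""
    return {t: composite.pixels[..., k]
            for k, t in enumerate(composite.spec.source_types)}
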