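"""Synthetic radial-EBUS phantom cohorts.

Real radial endobronchial ultrasound (EBUS) frames show a dark central
probe surrounded by speckled tissue, with the lesion wrapped around the
probe.  This module renders a first-order surrogate of that geometry so the
whole classification pipeline (cropping, polar unwrapping, multi-scale
composition, two-stage training, evaluation) can be exercised end-to-end
with known labels:

* a dark probe disk at a recorded centre with a cm calibration,
* one lesion region centred near the probe,
* class-conditioned lesion appearance — benign lesions are homogeneous
  hypoechoic disks with smooth circular boundaries, malignant lesions have
  heterogeneous interior texture and radially perturbed (irregular)
  boundaries,
* multiplicative log-normal speckle over the whole field.

Frames of one case share lesion shape and texture and differ only by a
small pose jitter, mimicking consecutive video frames.  All randomness is
derived from explicit seeds, so regenerating a cohort is byte-identical.

The default cohort is 13 benign and 82 malignant cases with 12 frames per
case (1140 frames), the case imbalance this kind of clinical EBUS archive
exhibits.  ``class_contrast`` controls how far apart the per-case
appearance-strength distributions of the two classes sit: at 1.0 the
classes are engineered to be separable, below 1.0 each case's strength is
a noisy draw around its class value, producing genuinely ambiguous cases
for studying imbalance mitigation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import ConfigurationError, DataError

BENIGN = "benign"
MALIGNANT = "malignant"
LABELS = (BENIGN, MALIGNANT)

# Echo levels of the piecewise template (8-bit scale).
_BG_LEVEL = 120.0
_LESION_LEVEL = 60.0
_PROBE_LEVEL = 15.0
_TEXTURE_AMP = 45.0       # peak heterogeneous-texture amplitude (malignant)
_IRREGULARITY = 0.10      # peak relative radial boundary perturbation


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, cohort size and noise settings of the synthetic cohort."""

    image_size_px: int = 256
    pixels_per_cm: float = 50.0
    probe_radius_cm: float = 0.25
    n_cases_benign: int = 13
    n_cases_malignant: int = 82
    frames_per_case: int = 12
    speckle_scale: float = 0.12
    lesion_radius_range_cm: tuple[float, float] = (0.5, 0.9)
    class_contrast: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size_px < 2 * 2.0 * self.pixels_per_cm:
            raise ConfigurationError(
                "image_size_px must be >= 2 * 2 cm * pixels_per_cm "
                f"({self.image_size_px} < {2 * 2.0 * self.pixels_per_cm}) "
                "so a 4 x 4 cm Type-1 crop fits"
            )
        lo, hi = self.lesion_radius_range_cm
        if not (0 < lo <= hi):
            raise ConfigurationError(
                f"lesion_radius_range_cm low <= high violated: ({lo}, {hi})"
            )
        if not self.probe_radius_cm < lo:
            raise ConfigurationError(
                f"probe_radius_cm ({self.probe_radius_cm}) must be smaller than "
                f"the minimum lesion radius ({lo})"
            )
        if self.pixels_per_cm <= 0 or self.probe_radius_cm <= 0:
            raise ConfigurationError("pixels_per_cm and probe_radius_cm must be positive")
        if self.frames_per_case <= 0:
            raise ConfigurationError("frames_per_case must be positive")
        if self.n_cases_benign < 0 or self.n_cases_malignant < 0:
            raise ConfigurationError("case counts must be non-negative")
        if self.speckle_scale < 0:
            raise ConfigurationError("speckle_scale must be non-negative")
        if not 0.0 <= self.class_contrast <= 1.0:
            raise ConfigurationError("class_contrast must lie in [0, 1]")


@dataclass
class CaseRecord:
    """One patient case: label, frames, probe geometry and calibration."""

    case_id: str
    label: str
    frame_paths: list[str]
    probe_center_px: tuple[int, int]
    pixels_per_cm: float
    frames: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def label_index(self) -> int:
        return LABELS.index(self.label)

    def load_frames(self) -> list[np.ndarray]:
        """Frames as uint8 RGB arrays, from memory if attached else from disk."""
        if self.frames is not None:
            return self.frames
        return [iio.imread(p) for p in self.frame_paths]


def _case_params(config: PhantomConfig, label: str, case_seed: int) -> dict:
    """Case-level draw: pose, lesion geometry, boundary harmonics, texture."""
    rng = np.random.default_rng(case_seed)
    half = config.image_size_px // 2
    probe_center = (half + int(rng.integers(-5, 6)), half + int(rng.integers(-5, 6)))
    radius_px = rng.uniform(*config.lesion_radius_range_cm) * config.pixels_per_cm
    ang = rng.uniform(0, 2 * np.pi)
    dist = rng.uniform(0, 0.2) * radius_px
    lesion_center = (probe_center[0] + dist * np.sin(ang),
                     probe_center[1] + dist * np.cos(ang))
    # Boundary irregularity and interior heterogeneity scale with a per-case
    # appearance strength: 1 for malignant, 0 for benign at full contrast.
    # Below full contrast the strength is a noisy draw around the class
    # value, so the classes overlap through genuinely ambiguous cases.
    base = 1.0 if label == MALIGNANT else 0.0
    if config.class_contrast >= 1.0:
        strength = base
    else:
        sigma = 0.5 * (1.0 - config.class_contrast)
        strength = float(np.clip(rng.normal(base, sigma), 0.0, 1.0))
    harmonics = rng.integers(3, 7, size=4)
    amplitudes = rng.uniform(0.5, 1.0, size=4)
    amplitudes *= _IRREGULARITY * strength / amplitudes.sum()
    phases = rng.uniform(0, 2 * np.pi, size=4)
    n_waves = 6
    tex_freq = rng.uniform(0.5, 1.2, size=n_waves)
    tex_dir = rng.uniform(0, 2 * np.pi, size=n_waves)
    tex_phase = rng.uniform(0, 2 * np.pi, size=n_waves)
    tex_weight = rng.uniform(0.5, 1.0, size=n_waves)
    tex_weight *= _TEXTURE_AMP * strength / tex_weight.sum()
    return {
        "probe_center": probe_center,
        "radius_px": radius_px,
        "lesion_center": lesion_center,
        "harmonics": harmonics,
        "amplitudes": amplitudes,
        "phases": phases,
        "tex_freq": tex_freq,
        "tex_dir": tex_dir,
        "tex_phase": tex_phase,
        "tex_weight": tex_weight,
    }


def _frame_seed_seq(case_seed: int, frame_index: int) -> np.random.SeedSequence:
    # Frame-level stream derived from (case seed, frame index) so no
    # per-frame state needs storing.
    return np.random.SeedSequence([case_seed, frame_index])


def generate_phantom_frame(config: PhantomConfig, label: str, case_seed: int,
                           frame_index: int) -> np.ndarray:
    """Render one uint8 RGB frame, deterministic in all four arguments."""
    config.validate()
    if label not in LABELS:
        raise ConfigurationError(f"label must be one of {LABELS}, got {label!r}")
    p = _case_params(config, label, case_seed)
    rng = np.random.default_rng(_frame_seed_seq(case_seed, frame_index))
    # small per-frame pose jitter: translation and rotation of the lesion
    jitter_rc = rng.uniform(-2.0, 2.0, size=2)
    jitter_theta = rng.uniform(-0.1, 0.1)

    n = config.image_size_px
    rows, cols = np.mgrid[0:n, 0:n].astype(np.float64)
    lc_r = p["lesion_center"][0] + jitter_rc[0]
    lc_c = p["lesion_center"][1] + jitter_rc[1]
    dr, dc = rows - lc_r, cols - lc_c
    r = np.hypot(dr, dc)
    phi = np.arctan2(dr, dc)

    boundary = np.ones_like(phi) * p["radius_px"]
    pert = np.zeros_like(phi)
    for k, a, ph in zip(p["harmonics"], p["amplitudes"], p["phases"]):
        pert += a * np.sin(k * (phi + jitter_theta) + ph)
    boundary *= 1.0 + pert
    lesion_mask = r <= boundary

    img = np.full((n, n), _BG_LEVEL)
    img[lesion_mask] = _LESION_LEVEL
    if p["tex_weight"].sum() > 0:
        ct, st = np.cos(jitter_theta), np.sin(jitter_theta)
        x = dc * ct - dr * st
        y = dc * st + dr * ct
        texture = np.zeros_like(img)
        for f, d, ph, w in zip(p["tex_freq"], p["tex_dir"], p["tex_phase"],
                               p["tex_weight"]):
            texture += w * np.sin(f * (x * np.cos(d) + y * np.sin(d)) + ph)
        img[lesion_mask] += texture[lesion_mask]

    pr, pc = p["probe_center"]
    probe_mask = np.hypot(rows - pr, cols - pc) <= config.probe_radius_cm * config.pixels_per_cm
    img[probe_mask] = _PROBE_LEVEL

    if config.speckle_scale > 0:
        img = img * np.exp(config.speckle_scale * rng.standard_normal((n, n)))

    img = np.floor(np.clip(img, 0, 255) + 0.5).astype(np.uint8)
    return np.stack([img, img, img], axis=-1)


def _case_seed(config: PhantomConfig, case_index: int) -> int:
    ss = np.random.SeedSequence([config.seed, case_index])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _iter_cases(config: PhantomConfig):
    idx = 0
    for i in range(config.n_cases_benign):
        yield f"b{i + 1:03d}", BENIGN, _case_seed(config, idx)
        idx += 1
    for i in range(config.n_cases_malignant):
        yield f"m{i + 1:03d}", MALIGNANT, _case_seed(config, idx)
        idx += 1


def simulate_cohort(config: PhantomConfig) -> list[CaseRecord]:
    """Generate a cohort in memory (frames attached to each record)."""
    config.validate()
    records = []
    for case_id, label, cseed in _iter_cases(config):
        params = _case_params(config, label, cseed)
        frames = [generate_phantom_frame(config, label, cseed, k)
                  for k in range(config.frames_per_case)]
        records.append(CaseRecord(
            case_id=case_id,
            label=label,
            frame_paths=[f"{case_id}_f{k:03d}.png" for k in range(config.frames_per_case)],
            probe_center_px=params["probe_center"],
            pixels_per_cm=config.pixels_per_cm,
            frames=frames,
        ))
    return records


MANIFEST_COLUMNS = ("case_id", "label", "frame_path", "probe_row", "probe_col",
                    "pixels_per_cm")


def generate_cohort(config: PhantomConfig, out_dir: str | Path) -> list[CaseRecord]:
    """Write one PNG per frame plus a CSV manifest; return the case records."""
    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    records = simulate_cohort(config)
    rows = []
    for rec in records:
        paths = []
        for rel, frame in zip(rec.frame_paths, rec.frames):
            path = frames_dir / rel
            iio.imwrite(path, frame)
            paths.append(str(path))
            rows.append((rec.case_id, rec.label, str(path),
                         rec.probe_center_px[0], rec.probe_center_px[1],
                         rec.pixels_per_cm))
        rec.frame_paths = paths
        rec.frames = None
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_COLUMNS)
        writer.writerows(rows)
    return records


def load_manifest(path: str | Path) -> list[CaseRecord]:
    """Read a cohort manifest (one row per frame) back into case records."""
    by_case: dict[str, CaseRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise DataError(f"manifest {path} lacks columns: {sorted(missing)}")
        for row in reader:
            cid = row["case_id"]
            if cid not in by_case:
                if row["label"] not in LABELS:
                    raise DataError(f"case {cid}: unknown label {row['label']!r}")
                by_case[cid] = CaseRecord(
                    case_id=cid,
                    label=row["label"],
                    frame_paths=[],
                    probe_center_px=(int(row["probe_row"]), int(row["probe_col"])),
                    pixels_per_cm=float(row["pixels_per_cm"]),
                )
            rec = by_case[cid]
            if row["label"] != rec.label:
                raise DataError(f"case {cid}: label changes across frames")
            rec.frame_paths.append(row["frame_path"])
    records = list(by_case.values())
    if not records:
        raise DataError(f"manifest {path} contains no cases")
    return records
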