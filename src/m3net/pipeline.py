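"""End-to-end orchestration: branch images -> stage 1 -> stage 2 -> metrics.

:func:`run_experiment` is the in-memory runner used by cross-validation and
the tests; :func:`run_pipeline` is the on-disk variant behind the CLI, with
config-hashed artifacts and idempotent resume.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np

from . import _nn as nn
from .encoders import Encoder, EncoderConfig, build_encoder, load_encoder, \
    save_encoder
from .errors import ConfigurationError, DataError
from .evaluation import MetricsReport, evaluate_scores, make_fold_plan
from .fusion import FusionConfig, FusionHead, align_branches
from .phantom import CaseRecord, load_manifest
from .training import BranchDataset, TrainConfig, build_dataset, \
    compute_class_weights, train_stage1, train_stage2


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: which branches, which encoder, which fusion variant."""

    branches: tuple[str, ...] = ("type4", "polar3")
    encoder_config: EncoderConfig = field(default_factory=EncoderConfig)
    fusion_variant: str = "ffm_v2"
    train_config: TrainConfig = field(default_factory=TrainConfig)

    def validate(self) -> None:
        if not 1 <= len(self.branches) <= 4:
            raise ConfigurationError("branch count must be between 1 and 4")
        if len(self.branches) >= 2 and self.fusion_variant not in (
                "ffm_v1", "ffm_v2", "ffm_v3"):
            raise ConfigurationError(
                "a fusion variant is required when fusing 2+ branches"
            )


@dataclass
class ExperimentResult:
    report: MetricsReport
    scores: np.ndarray
    labels: np.ndarray
    encoders: dict[str, Encoder]
    head: FusionHead | None
    histories: dict[str, list[dict]]


def _fusion_config_for(spec: ExperimentSpec, encoders: dict[str, Encoder],
                       ) -> FusionConfig:
    channels = tuple(e.feature_channels for e in encoders.values())
    widths = {e.fc_width for e in encoders.values()}
    return FusionConfig(variant=spec.fusion_variant, channel_counts=channels,
                        fc_width=widths.pop())


def make_forward(encoders: dict[str, Encoder], head: FusionHead | None,
                 fusion_variant: str):
    """Branch-batches -> logits, through frozen encoders (and fusion if any)."""
    def forward(batches):
        if head is None:
            (enc,) = encoders.values()
            with nn.no_grad():
                return enc(nn.Tensor(batches[0]))
        maps, fcs = [], []
        with nn.no_grad():
            for enc, xb in zip(encoders.values(), batches):
                x = nn.Tensor(xb)
                maps.append(enc.forward_features(x))
                if fusion_variant == "ffm_v3":
                    fcs.append(enc.forward_fc(x))
        return head(align_branches(maps), fcs if fusion_variant == "ffm_v3" else None)
    return forward


def _score_dataset(forward, ds: BranchDataset, batch_size: int) -> np.ndarray:
    from .training import predict_scores
    return predict_scores(forward, ds, batch_size=batch_size)


def run_experiment(spec: ExperimentSpec, train_records: list[CaseRecord],
                   valid_records: list[CaseRecord],
                   test_records: list[CaseRecord],
                   seed_offset: int = 0) -> ExperimentResult:
    """Train both stages on the given case-level splits, evaluate on test."""
    spec.validate()
    if not test_records:
        raise DataError("empty test split")
    config = replace(spec.train_config,
                     seed=spec.train_config.seed + 1000 * seed_offset)
    n_b = sum(1 for r in train_records if r.label == "benign")
    n_m = sum(1 for r in train_records if r.label == "malignant")
    weights = compute_class_weights(max(n_b, 1), max(n_m, 1))

    encoders: dict[str, Encoder] = {}
    histories: dict[str, list[dict]] = {}
    for i, branch in enumerate(spec.branches):
        branch_cfg = replace(config, seed=config.seed + i)
        enc, hist = train_stage1(branch, spec.encoder_config, train_records,
                                 valid_records, branch_cfg, weights=weights)
        enc.eval()
        encoders[branch] = enc
        histories[f"stage1/{branch}"] = hist

    head = None
    if len(spec.branches) >= 2:
        fusion_cfg = _fusion_config_for(spec, encoders)
        head, hist = train_stage2(encoders, fusion_cfg, train_records,
                                  valid_records, config, weights=weights)
        histories["stage2"] = hist

    forward = make_forward(encoders, head, spec.fusion_variant)
    test_ds = build_dataset(test_records, spec.branches, config.input_size)
    scores = _score_dataset(forward, test_ds, config.batch_size)
    report = evaluate_scores(scores, test_ds.labels)
    return ExperimentResult(report=report, scores=scores, labels=test_ds.labels,
                            encoders=encoders, head=head, histories=histories)


# -- on-disk pipeline ---------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Disk-backed pipeline run: manifest in, artifacts out."""

    manifest: str
    workdir: str
    spec: ExperimentSpec = field(default_factory=ExperimentSpec)
    split_seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def save_head(head: FusionHead, path: str | Path) -> None:
    payload = {f"param/{k}": v for k, v in head.state_dict().items()}
    header = asdict(head.config)
    buf = io.BytesIO()
    np.savez(buf, __config__=np.frombuffer(json.dumps(header).encode(),
                                           dtype=np.uint8), **payload)
    Path(path).write_bytes(buf.getvalue())


def load_head(path: str | Path) -> FusionHead:
    with np.load(Path(path), allow_pickle=False) as archive:
        header = json.loads(bytes(archive["__config__"]).decode())
        header["channel_counts"] = tuple(header["channel_counts"])
        header["spatial_size"] = tuple(header["spatial_size"])
        head = FusionHead(FusionConfig(**header), seed=0)
        head.load_state_dict({k[len("param/"):]: archive[k]
                              for k in archive.files if k.startswith("param/")})
    head.eval()
    return head


def run_pipeline(config: RunConfig) -> MetricsReport:
    """Execute the full pipeline with config-hashed, resumable artifacts.

    The cohort is split case-level (stratified) into train/valid/test; each
    stage writes a checkpoint keyed by the config hash and is skipped on
    rerun when its artifact already exists for the same hash.
    """
    config.spec.validate()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    snapshot = workdir / "run_config.json"
    if snapshot.exists():
        previous = json.loads(snapshot.read_text()).get("config_hash")
        if previous != chash:
            raise ConfigurationError(
                f"workdir {workdir} holds artifacts for config {previous}, "
                f"refusing to resume with config {chash}"
            )
    snapshot.write_text(json.dumps(
        {"config_hash": chash, "config": asdict(config)},
        indent=2, default=str))

    records = load_manifest(config.manifest)
    plan = make_fold_plan(records, n_folds=4, seed=config.split_seed)
    fold = plan.folds[0]
    by_id = {r.case_id: r for r in records}
    splits = {name: [by_id[i] for i in getattr(fold, name)]
              for name in ("train", "valid", "test")}

    spec = config.spec
    train_cfg = spec.train_config
    n_b = sum(1 for r in splits["train"] if r.label == "benign")
    n_m = sum(1 for r in splits["train"] if r.label == "malignant")
    weights = compute_class_weights(max(n_b, 1), max(n_m, 1))

    encoders: dict[str, Encoder] = {}
    for i, branch in enumerate(spec.branches):
        ckpt = workdir / f"encoder_{branch}_{chash}.npz"
        if ckpt.exists():
            encoders[branch] = load_encoder(ckpt)
            continue
        branch_cfg = replace(train_cfg, seed=train_cfg.seed + i)
        enc, hist = train_stage1(branch, spec.encoder_config, splits["train"],
                                 splits["valid"], branch_cfg, weights=weights)
        save_encoder(enc, ckpt)
        _append_log(workdir / "train.log", f"stage1/{branch}", hist)
        encoders[branch] = enc

    head = None
    if len(spec.branches) >= 2:
        ckpt = workdir / f"fusion_{chash}.npz"
        if ckpt.exists():
            head = load_head(ckpt)
        else:
            fusion_cfg = _fusion_config_for(spec, encoders)
            head, hist = train_stage2(encoders, fusion_cfg, splits["train"],
                                      splits["valid"], train_cfg, weights=weights)
            save_head(head, ckpt)
            _append_log(workdir / "train.log", "stage2", hist)

    forward = make_forward(encoders, head, spec.fusion_variant)
    test_ds = build_dataset(splits["test"], spec.branches, train_cfg.input_size)
    scores = _score_dataset(forward, test_ds, train_cfg.batch_size)
    report = evaluate_scores(scores, test_ds.labels)
    out = {"config_hash": chash, "metrics": report.as_dict(),
           "counts": asdict(report.counts), "roc": report.roc,
           "test_cases": fold.test}
    (workdir / "metrics.json").write_text(json.dumps(out, indent=2))
    return report


def _append_log(path: Path, stage: str, history: list[dict]) -> None:
    with open(path, "a") as fh:
        for row in history:
            fh.write(json.dumps({"stage": stage, **row}) + "\n")
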