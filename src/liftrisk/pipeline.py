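"""End-to-end pipeline: simulate/load -> segment -> features -> screen -> fit.

``run_pipeline`` chains the stages on either a synthetic cohort or a
directory of recording CSVs, persists every intermediate artifact when an
output directory is given, and collects a run manifest (configuration
snapshot, per-stage seeds, stage warnings) so deterministic stages can be
reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as lio
from .features import build_feature_table, feature_columns
from .model import ModelReport, fit_classifier, prune_correlated, remove_outliers
from .screen import ScreenResult, screen_features
from .signal import SegmentConfig, bandpass, segment_recording
from .synth import SynthConfig, generate_cohort

logger = logging.getLogger("liftrisk")


@dataclass
class PipelineConfig:
    seed: int = 0
    input_dir: str | None = None  # None -> synthetic cohort
    synth: SynthConfig = field(default_factory=SynthConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    screen_alpha: float = 0.05
    pairing: str = "lift"
    r_threshold: float = 0.7
    model_alpha: float = 0.05
    or_epsilon: float = 0.01
    # the replication chain prunes correlation on all 114 features and lets the
    # logistic Wald tests drop the non-significant ones; significant_only
    # restricts the candidate set to screening-significant features first
    significant_only: bool = False
    expected_lifts: int | None = 20

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        kwargs = dict(raw)
        if "synth" in kwargs and isinstance(kwargs["synth"], dict):
            _check_fields(SynthConfig, kwargs["synth"], "synth")
            if "amplitudes" in kwargs["synth"]:
                kwargs["synth"]["amplitudes"] = dict(kwargs["synth"]["amplitudes"])
            if "burst_band_hz" in kwargs["synth"]:
                kwargs["synth"]["burst_band_hz"] = tuple(kwargs["synth"]["burst_band_hz"])
            if "burst_duration_s" in kwargs["synth"]:
                kwargs["synth"]["burst_duration_s"] = tuple(kwargs["synth"]["burst_duration_s"])
            kwargs["synth"] = SynthConfig(**kwargs["synth"])
        if "segment" in kwargs and isinstance(kwargs["segment"], dict):
            _check_fields(SegmentConfig, kwargs["segment"], "segment")
            kwargs["segment"] = SegmentConfig(**kwargs["segment"])
        return cls(**kwargs)


def _check_fields(cls, raw: dict, where: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config fields under '{where}': "
                         + ", ".join(f"{where}.{b}" for b in sorted(bad)))


@dataclass
class PipelineResult:
    feature_table: pd.DataFrame
    screen_results: list[ScreenResult]
    model_report: ModelReport
    manifest: dict


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _load_recordings(input_dir: str) -> list:
    paths = sorted(Path(input_dir).glob("*.csv"))
    paths = [p for p in paths if p.stem != "truth"]
    if not paths:
        raise FileNotFoundError(f"no recording CSVs found in {input_dir}")
    return [lio.read_recording(p) for p in paths]


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute segment -> features -> screen -> fit on a cohort.

    With ``config.input_dir`` unset, a synthetic cohort is generated from
    ``config.synth`` and ``config.seed``.  Returns the feature table, the
    screening results, the model report and the run manifest.
    """
    collector = _WarningCollector()
    root_logger = logging.getLogger("liftrisk")
    root_logger.addHandler(collector)
    try:
        return _run(config, out_dir, collector)
    finally:
        root_logger.removeHandler(collector)


def _run(config, out_dir, collector) -> PipelineResult:
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if config.input_dir is None:
        recordings, truth = generate_cohort(config.synth, seed=config.seed)
    else:
        recordings = _load_recordings(config.input_dir)
        truth = None

    seg_conf = dataclasses.replace(
        config.segment, expected_count=config.expected_lifts
    )
    rois = {}
    filtered = {}
    for rec in recordings:
        key = (rec.subject_id, rec.trial_label)
        rois[key] = segment_recording(rec, seg_conf)
        filtered[key] = {
            ch: bandpass(rec.channels[ch], rec.fs, seg_conf.low_hz,
                         seg_conf.high_hz, seg_conf.order)
            for ch in rec.channels
        }

    table = build_feature_table(recordings, rois, filtered=filtered)
    screen_results = screen_features(
        table, alpha=config.screen_alpha, pairing=config.pairing
    )

    candidates = feature_columns()
    if config.significant_only:
        significant = {r.feature for r in screen_results if r.significant}
        candidates = [f for f in candidates if f in significant]
    kept = prune_correlated(table, candidates, r_threshold=config.r_threshold)
    max_k = len(table) // 5
    if len(kept) > max_k:
        # small cohorts cannot support one predictor per <5 rows; keep the
        # screening-strongest features up to that budget
        p_by_feature = {r.feature: r.p_value for r in screen_results}
        kept = sorted(kept, key=lambda f: p_by_feature.get(f, 1.0))[:max_k]
        kept = [f for f in feature_columns() if f in kept]  # restore order
        logger.warning("candidate features capped at %d (n=%d rows)",
                       max_k, len(table))
    pruned, removed_ids = remove_outliers(table, kept, table["label"])
    removed_per_class = (
        table.loc[removed_ids, "label"].value_counts().to_dict() if removed_ids else {}
    )
    report = fit_classifier(
        pruned, kept,
        alpha=config.model_alpha, or_epsilon=config.or_epsilon,
    )
    report.removed_outliers = [int(i) for i in removed_ids]
    report.removed_per_class = {str(k): int(v) for k, v in removed_per_class.items()}

    manifest = {
        "schema_version": lio.SCHEMA_VERSION,
        "seed": config.seed,
        "config": _snapshot(config),
        "n_recordings": len(recordings),
        "n_instances": int(len(table)),
        "n_instances_after_outliers": int(len(pruned)),
        "n_removed_outliers": len(removed_ids),
        "warnings": list(collector.messages),
        "input_digest": _digest(table),
    }

    if out is not None:
        lio.write_feature_table(table, out / "features.csv")
        lio.write_screen_results(screen_results, out / "screen.csv")
        lio.write_model_report(report, out / "report.json")
        lio.write_manifest(manifest, out / "manifest.json")
        roi_frames = [
            pd.DataFrame({
                "subject": key[0], "trial": key[1],
                "lift_index": range(len(r)),
                "start": [x.start for x in r], "end": [x.end for x in r],
            })
            for key, r in rois.items()
        ]
        pd.concat(roi_frames, ignore_index=True).to_csv(out / "rois.csv", index=False)
        if truth is not None:
            truth.to_csv(out / "truth.csv", index=False)

    return PipelineResult(table, screen_results, report, manifest)


def _snapshot(config: PipelineConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return convert(config)


def _digest(table: pd.DataFrame) -> str:
    payload = table.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()
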