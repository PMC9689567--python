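"""Plain-text file formats for recordings, ROIs, feature tables and reports.

A recording is a CSV with header ``t,ax,ay,az,vx,vy,vz`` plus a sidecar JSON
(same stem, ``.json`` extension) carrying ``subject_id``, ``trial_label``,
``fs`` and units.  All other artifacts are flat CSV or JSON.  Schemas are
deliberately simple and inspectable; every writer/reader pair round-trips
losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import ID_COLUMNS, feature_columns
from .model import ModelReport
from .screen import ScreenResult, screen_to_frame
from .signal import CHANNELS, ImuRecording, LiftROI

SCHEMA_VERSION = "1"

_UNITS = {"a": "m/s^2", "v": "rad/s"}


def write_recording(rec: ImuRecording, csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    t = np.arange(rec.n_samples) / rec.fs
    frame = pd.DataFrame({"t": t, **{c: rec.channels[c] for c in CHANNELS}})
    frame.to_csv(csv_path, index=False, float_format="%.9g")
    meta = {
        "schema_version": SCHEMA_VERSION,
        "subject_id": rec.subject_id,
        "trial_label": rec.trial_label,
        "fs": rec.fs,
        "units": {c: _UNITS[c[0]] for c in CHANNELS},
    }
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_recording(csv_path: str | Path) -> ImuRecording:
    csv_path = Path(csv_path)
    sidecar = csv_path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sidecar metadata not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    frame = pd.read_csv(csv_path)
    missing = [c for c in CHANNELS if c not in frame.columns]
    if missing:
        raise ValueError(f"{csv_path}: missing channels {missing}")
    if frame[list(CHANNELS)].isna().any().any():
        raise ValueError(f"{csv_path}: recording contains gaps (NaN samples)")
    return ImuRecording(
        subject_id=str(meta["subject_id"]),
        trial_label=str(meta["trial_label"]),
        fs=float(meta["fs"]),
        channels={c: frame[c].to_numpy(dtype=float) for c in CHANNELS},
    )


def write_rois(
    rois: list[LiftROI], subject: str, trial: str, path: str | Path
) -> None:
    frame = pd.DataFrame({
        "subject": subject,
        "trial": trial,
        "lift_index": range(len(rois)),
        "start": [r.start for r in rois],
        "end": [r.end for r in rois],
    })
    frame.to_csv(path, index=False)


def read_rois(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"subject", "trial", "lift_index", "start", "end"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing ROI columns {sorted(missing)}")
    return frame


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing identifier columns {missing}")
    absent = [c for c in feature_columns() if c not in table.columns]
    if absent:
        raise ValueError(f"{path}: missing {len(absent)} feature columns")
    return table


def write_screen_results(results: list[ScreenResult], path: str | Path) -> None:
    path = Path(path)
    frame = screen_to_frame(results)
    frame.to_csv(path, index=False, float_format="%.12g")
    path.with_suffix(".json").write_text(
        json.dumps(frame.to_dict(orient="records"), indent=2)
    )


def write_model_report(report: ModelReport, path: str | Path) -> None:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=2))
    cm_path = path.with_name(path.stem + "_confusion.csv")
    cm = pd.DataFrame(
        report.metrics.confusion,
        index=["NO_RISK", "RISK"],
        columns=["pred_NO_RISK", "pred_RISK"],
    )
    cm.to_csv(cm_path)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
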