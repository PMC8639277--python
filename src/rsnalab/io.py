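"""Plain-text persistence of subject records and analysis outputs.

A subject directory holds:

* ``channels.csv`` -- header ``time_s,pressure_mmHg,rsna_uV`` (UTF-8, '.'
  decimal, LF line endings);
* ``events.csv`` -- header ``time_s,agent,dose,dose_units``;
* ``record.json`` -- sampling rate, group, background level, and (for
  simulated subjects) the generator ground truth.

Analysis writers emit the beat table, the baroreflex curve and a JSON
report per subject.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .baroreflex import BaroreflexCurve
from .core import DataError, SubjectRecord, Trace
from .model import RSNAResults

__all__ = [
    "write_record",
    "read_record",
    "write_results",
]

CHANNELS_FILE = "channels.csv"
EVENTS_FILE = "events.csv"
SIDECAR_FILE = "record.json"


def write_record(record: SubjectRecord, directory: str | Path) -> Path:
    """Write one subject to ``directory`` (created if needed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "time_s": record.pressure.times,
            "pressure_mmHg": record.pressure.values,
            "rsna_uV": record.rsna_raw.values,
        }
    )
    df.to_csv(directory / CHANNELS_FILE, index=False, float_format="%.6g", lineterminator="\n")
    record.events.to_csv(directory / EVENTS_FILE, index=False, lineterminator="\n")
    sidecar = {
        "subject_id": record.subject_id,
        "group": record.group,
        "sampling_rate": record.sampling_rate,
        "background_uv": record.background_uv,
        "meta": record.meta,
        "truth": record.truth,
    }
    (directory / SIDECAR_FILE).write_text(json.dumps(sidecar, indent=1), encoding="utf-8")
    return directory


def read_record(directory: str | Path) -> SubjectRecord:
    """Read a subject directory written by :func:`write_record`."""
    directory = Path(directory)
    sidecar = json.loads((directory / SIDECAR_FILE).read_text(encoding="utf-8"))
    df = pd.read_csv(directory / CHANNELS_FILE)
    for col in ("time_s", "pressure_mmHg", "rsna_uV"):
        if col not in df.columns:
            raise DataError(f"{CHANNELS_FILE} missing column {col!r}")
    fs = float(sidecar["sampling_rate"])
    start = float(df["time_s"].iloc[0])
    events = pd.read_csv(directory / EVENTS_FILE)
    if events.empty:
        events = pd.DataFrame(columns=["time_s", "agent", "dose", "dose_units"])
    return SubjectRecord(
        subject_id=str(sidecar["subject_id"]),
        group=str(sidecar["group"]),
        pressure=Trace(df["pressure_mmHg"].to_numpy(), fs, start_time=start, unit="mmHg"),
        rsna_raw=Trace(df["rsna_uV"].to_numpy(), fs, start_time=start, unit="uV"),
        events=events,
        background_uv=float(sidecar.get("background_uv", 0.0)),
        truth=sidecar.get("truth", {}),
        meta=sidecar.get("meta", {}),
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_results(results: RSNAResults, directory: str | Path) -> Path:
    """Write per-subject analysis outputs (beats, curve, JSON report)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    results.beats.to_frame().to_csv(directory / "beats.csv", index=False, float_format="%.6g")
    if results.curve is not None:
        results.curve.to_frame().to_csv(
            directory / "baroreflex_curve.csv", index=False, float_format="%.6g"
        )
    report = {
        "subject_id": results.subject_id,
        "group": results.group,
        "control_window_s": list(results.control_window),
        "control_mbp_mmhg": results.control_mbp,
        "control_hr_bpm": results.control_hr,
        "control_rsna_uvs": results.mean_rsna_uvs,
        "burst": None
        if results.burst is None
        else {
            "mean_rsna_uvs_per_bin": results.burst.mean_rsna,
            "max_over_mean": results.burst.max_over_mean,
            "min_over_mean": results.burst.min_over_mean,
            "extremum_mode": results.burst.extremum_mode,
        },
        "coupling": None
        if results.coupling is None
        else {
            "r": results.coupling.r,
            "best_lag_beats": results.coupling.best_lag,
            "classification": results.coupling.classification,
            "threshold": results.coupling.threshold,
        },
        "slope_pct_per_mmhg": None if results.slope is None else results.slope.slope,
        "plateau_mmhg": results.plateau_mmhg,
        "responses": [
            {
                "agent": r.agent,
                "baseline_mbp": r.baseline_mbp,
                "baseline_hr": r.baseline_hr,
                "delta_mbp": r.delta_mbp,
                "delta_hr": r.delta_hr,
                "rsna_inhibition_pct": r.rsna_inhibition_pct,
                "time_of_extremum": r.time_of_extremum,
                "flags": list(r.flags),
            }
            for r in results.responses
        ],
        "settings": results.settings,
    }
    (directory / "report.json").write_text(
        json.dumps(report, indent=1, default=_json_default, allow_nan=True), encoding="utf-8"
    )
    return directory
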