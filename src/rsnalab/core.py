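"""Core containers and errors shared across the analysis pipeline.

The pipeline manipulates three kinds of series:

* :class:`Trace` -- a uniformly sampled, unit-tagged channel (arterial
  pressure in mmHg, raw or rectified nerve signal in microvolts).
* :class:`IntegratedSeries` -- rectified nerve activity integrated over
  contiguous, half-open time bins (the "uV/100 ms" and "uV/s" series).
* :class:`BeatSeries` -- detected systolic peak times with inter-beat
  intervals and instantaneous heart rate.

A :class:`SubjectRecord` bundles one animal's channels with its event
markers (drug administrations) and acquisition metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "IntegratedSeries",
    "BeatSeries",
    "SubjectRecord",
    "RsnaError",
    "ConfigurationError",
    "DataError",
    "AlignmentError",
    "StateError",
    "FlatSignalError",
    "DegenerateSeriesError",
    "InsufficientRangeError",
    "NoPlateauError",
]


class RsnaError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RsnaError, ValueError):
    """Invalid parameter or simulation configuration."""


class DataError(RsnaError, ValueError):
    """Input data violates a precondition (non-finite, too short, ...)."""


class AlignmentError(DataError):
    """Two series that must share a time base do not."""


class StateError(RsnaError, RuntimeError):
    """Operation applied in an invalid state (e.g. double background correction)."""


class FlatSignalError(DataError):
    """Pressure channel carries no detectable pulse."""


class DegenerateSeriesError(DataError):
    """Series has zero variance / zero mean where a ratio is required."""


class InsufficientRangeError(DataError):
    """Baroreflex curve does not span enough pressure bins or transition."""


class NoPlateauError(DataError):
    """Baroreflex curve never flattens into a lower plateau."""


def _as_float_array(values: Any, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DataError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size and not np.all(np.isfinite(arr)):
        raise DataError(f"{name} contains non-finite samples")
    return arr


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled, unit-tagged time series."""

    values: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    unit: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_float_array(self.values, "Trace.values"))
        if not self.sampling_rate > 0:
            raise ConfigurationError("sampling_rate must be positive")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.n * self.dt

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) / self.sampling_rate

    def index_at(self, t: float) -> int:
        """Index of the sample at (or immediately before) time ``t``."""
        i = int(np.floor((t - self.start_time) * self.sampling_rate))
        return min(max(i, 0), self.n - 1)

    def segment(self, t0: float, t1: float) -> "Trace":
        """Samples with times in the half-open window ``[t0, t1)``."""
        i0 = int(np.ceil((t0 - self.start_time) * self.sampling_rate - 1e-9))
        i1 = int(np.ceil((t1 - self.start_time) * self.sampling_rate - 1e-9))
        i0, i1 = max(i0, 0), min(max(i1, 0), self.n)
        return Trace(
            self.values[i0:i1],
            self.sampling_rate,
            start_time=self.start_time + i0 * self.dt,
            unit=self.unit,
        )

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Trace":
        return replace(self, values=values, unit=self.unit if unit is None else unit)


@dataclass(frozen=True)
class IntegratedSeries:
    """Per-bin integrals of a rectified trace (uV*s per half-open bin)."""

    bin_start_times: np.ndarray
    bin_width: float
    values: np.ndarray
    unit: str = "uV*s"
    background_corrected: bool = False

    def __post_init__(self) -> None:
        starts = _as_float_array(self.bin_start_times, "bin_start_times")
        vals = _as_float_array(self.values, "values")
        if starts.size != vals.size:
            raise DataError("bin_start_times and values must have equal length")
        if not self.bin_width > 0:
            raise ConfigurationError("bin_width must be positive")
        if starts.size > 1 and not np.allclose(np.diff(starts), self.bin_width, rtol=1e-6):
            raise DataError("bins must be contiguous with spacing bin_width")
        object.__setattr__(self, "bin_start_times", starts)
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def start_time(self) -> float:
        return float(self.bin_start_times[0]) if self.n else 0.0

    @property
    def end_time(self) -> float:
        return float(self.bin_start_times[-1] + self.bin_width) if self.n else 0.0

    def window_mask(self, t0: float, t1: float) -> np.ndarray:
        """Bins fully contained in ``[t0, t1)`` (up to numerical slack)."""
        eps = 1e-9 * max(1.0, abs(t1))
        return (self.bin_start_times >= t0 - eps) & (
            self.bin_start_times + self.bin_width <= t1 + eps
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_start_s": self.bin_start_times, "value": self.values})


# Physiological guard band for rat instantaneous heart rate (bpm).
HR_GUARD_BPM = (100.0, 700.0)


@dataclass(frozen=True)
class BeatSeries:
    """Systolic peak times; inter-beat intervals and HR are derived."""

    peak_times: np.ndarray
    refractory_s: float = 0.08

    def __post_init__(self) -> None:
        times = _as_float_array(self.peak_times, "peak_times")
        if times.size < 2:
            raise DataError("a BeatSeries needs at least two systolic peaks")
        d = np.diff(times)
        if np.any(d <= 0):
            raise DataError("peak_times must be strictly increasing")
        if np.any(d < self.refractory_s - 1e-12):
            raise DataError("inter-beat interval shorter than the refractory period")
        hr = 60.0 / d
        lo, hi = HR_GUARD_BPM
        if np.any(hr < lo) or np.any(hr > hi):
            raise DataError(
                f"instantaneous HR outside the physiological guard band {HR_GUARD_BPM} bpm"
            )
        object.__setattr__(self, "peak_times", times)

    @property
    def n_beats(self) -> int:
        return self.peak_times.size

    @property
    def ibi(self) -> np.ndarray:
        """Inter-beat intervals, one per beat ``[peak_i, peak_{i+1})``."""
        return np.diff(self.peak_times)

    @property
    def hr_inst(self) -> np.ndarray:
        """Instantaneous heart rate (bpm), one per inter-beat interval."""
        return 60.0 / self.ibi

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "peak_time_s": self.peak_times[:-1],
                "ibi_s": self.ibi,
                "hr_bpm": self.hr_inst,
            }
        )


EVENT_COLUMNS = ("time_s", "agent", "dose", "dose_units")


@dataclass
class SubjectRecord:
    """One animal's channels, event markers and acquisition metadata.

    ``truth`` holds generator ground truth (beat times, preset parameters)
    for testing only; no analysis routine reads it.
    """

    subject_id: str
    group: str
    pressure: Trace
    rsna_raw: Trace
    events: pd.DataFrame
    background_uv: float = 0.0
    truth: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise DataError(f"event table missing columns {missing}")
        if self.pressure.n != self.rsna_raw.n or not np.isclose(
            self.pressure.sampling_rate, self.rsna_raw.sampling_rate
        ):
            raise AlignmentError("pressure and RSNA channels must share the time base")
        if self.background_uv < 0:
            raise ConfigurationError("background_uv must be >= 0")

    @property
    def sampling_rate(self) -> float:
        return self.pressure.sampling_rate

    @property
    def duration(self) -> float:
        return self.pressure.duration

    def first_event_time(self) -> float | None:
        if len(self.events) == 0:
            return None
        return float(self.events["time_s"].min())
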