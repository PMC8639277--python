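"""Nerve-signal conditioning: rectification, fixed-bin integration,
residual-background correction and normalization to percent of control.

These are the digital equivalents of the hardware chain used for multiunit
sympathetic recordings: the raw bipolar signal is full-wave rectified, the
rectified signal is integrated over fixed bins (100 ms for burst analysis,
1 s for the mean-activity series), the residual electrical output measured
after nerve blockade is subtracted, and -- because absolute microvolt values
are electrode-dependent -- every subject is expressed in percent of its own
control-period mean.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import (
    ConfigurationError,
    DataError,
    DegenerateSeriesError,
    IntegratedSeries,
    StateError,
    Trace,
)

__all__ = [
    "rectify",
    "integrate_bins",
    "subtract_background",
    "percent_of_control",
    "percent_of_control_values",
]


def rectify(raw: Trace, dc: float | None = None, dc_window_s: float | None = 1.0) -> Trace:
    """Full-wave rectify a raw nerve trace after DC removal.

    Parameters
    ----------
    raw
        Raw bipolar nerve signal (uV). Must contain only finite samples
        (enforced by :class:`Trace`).
    dc
        Explicit DC estimate to subtract. When given it takes precedence.
    dc_window_s
        Width of the sliding-mean window used to estimate a slowly varying
        DC offset (AC-coupling emulation). ``None`` disables DC removal.
    """
    x = raw.values
    if dc is not None:
        base = float(dc)
    elif dc_window_s is not None:
        if dc_window_s <= 0:
            raise ConfigurationError("dc_window_s must be positive")
        size = max(int(round(dc_window_s * raw.sampling_rate)), 1)
        if size >= x.size:
            base = x.mean() if x.size else 0.0
        else:
            base = uniform_filter1d(x, size=size, mode="nearest")
    else:
        base = 0.0
    return raw.with_values(np.abs(x - base), unit="uV")


def integrate_bins(rectified: Trace, bin_width: float) -> IntegratedSeries:
    """Integrate a rectified trace over contiguous half-open bins.

    Uses the rectangular rule (sum of samples times the sample period),
    matching an analog integrate-and-dump stage and making the
    sum-over-bins == whole-window-integral identity exact. Bins are
    anchored at the trace start; a trailing partial bin is dropped.
    """
    dt = rectified.dt
    if bin_width < dt - 1e-12:
        raise ConfigurationError("bin_width must be at least one sample period")
    m_float = bin_width / dt
    m = int(round(m_float))
    if abs(m_float - m) > 1e-6 * m_float:
        raise ConfigurationError("bin_width must be an integer multiple of the sample period")
    n_bins = rectified.n // m
    if n_bins == 0:
        raise DataError("trace shorter than one bin")
    vals = rectified.values[: n_bins * m].reshape(n_bins, m).sum(axis=1) * dt
    starts = rectified.start_time + np.arange(n_bins) * bin_width
    return IntegratedSeries(starts, bin_width, vals, unit="uV*s")


def subtract_background(series: IntegratedSeries, background_uv: float) -> IntegratedSeries:
    """Subtract the residual electrical output from each bin.

    ``background_uv`` is the rectified-mean background level (uV), i.e. the
    residual output measured after nerve blockade; each bin loses
    ``background_uv * bin_width`` and negative results are clipped to zero.
    """
    if series.background_corrected:
        raise StateError("series is already background-corrected")
    if background_uv < 0:
        raise ConfigurationError("background_uv must be >= 0")
    corrected = np.clip(series.values - background_uv * series.bin_width, 0.0, None)
    return IntegratedSeries(
        series.bin_start_times,
        series.bin_width,
        corrected,
        unit=series.unit,
        background_corrected=True,
    )


def percent_of_control(
    series: IntegratedSeries,
    control_window: tuple[float, float],
    min_control_s: float = 30.0,
) -> IntegratedSeries:
    """Express each bin in percent of the control-window mean.

    The control window averages 100% by construction; change from control
    is ``value - 100`` (a fully silenced bin reads 0%, i.e. -100%).
    """
    t0, t1 = control_window
    if t1 - t0 < min_control_s:
        raise ConfigurationError(
            f"control window must span at least {min_control_s} s (got {t1 - t0:g} s)"
        )
    if t0 < series.start_time - 1e-9 or t1 > series.end_time + 1e-9:
        raise ConfigurationError("control window lies outside the series")
    mask = series.window_mask(t0, t1)
    if not mask.any():
        raise DataError("control window contains no complete bins")
    control_mean = float(series.values[mask].mean())
    if control_mean <= 0:
        raise DegenerateSeriesError("control mean must be positive")
    return IntegratedSeries(
        series.bin_start_times,
        series.bin_width,
        100.0 * series.values / control_mean,
        unit="%",
        background_corrected=series.background_corrected,
    )


def percent_of_control_values(
    values: np.ndarray,
    times: np.ndarray,
    control_window: tuple[float, float],
    min_control_s: float = 30.0,
) -> np.ndarray:
    """Percent-of-control for an irregular (e.g. per-beat) series."""
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    t0, t1 = control_window
    if t1 - t0 < min_control_s:
        raise ConfigurationError(
            f"control window must span at least {min_control_s} s (got {t1 - t0:g} s)"
        )
    mask = (times >= t0) & (times < t1)
    if not mask.any():
        raise DataError("control window contains no samples")
    control_mean = float(values[mask].mean())
    if control_mean <= 0:
        raise DegenerateSeriesError("control mean must be positive")
    return 100.0 * values / control_mean
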