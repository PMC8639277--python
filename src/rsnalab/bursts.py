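"""Basal bursting-activity metrics from the 100-ms integrated series.

Because absolute microvolt values are electrode-dependent, burst amplitude
is characterized by dimensionless ratios over a fixed analysis window
(60 s of the control period by convention): the maximal and minimal bin
values referred to the window mean. Reduced max/mean with raised min/mean
indicates a higher tonic floor with smaller superimposed bursts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ConfigurationError, DataError, DegenerateSeriesError, IntegratedSeries

__all__ = ["BurstMetrics", "burst_stats"]


@dataclass(frozen=True)
class BurstMetrics:
    window: tuple[float, float]
    mean_rsna: float
    max_over_mean: float
    min_over_mean: float
    extremum_mode: str
    n_bins: int


def burst_stats(
    series: IntegratedSeries,
    window: tuple[float, float],
    extremum_mode: str = "single",
    top_k: int = 5,
    min_bins: int = 1,
) -> BurstMetrics:
    """Burst amplitude ratios over ``window`` of a 100-ms integrated series.

    ``extremum_mode='single'`` uses the single largest/smallest bin
    (literal max/mean and min/mean); ``'top_k_mean'`` averages the ``top_k``
    most extreme bins on each side for noise robustness. The mode used is
    recorded in the result.
    """
    if extremum_mode not in ("single", "top_k_mean"):
        raise ConfigurationError("extremum_mode must be 'single' or 'top_k_mean'")
    t0, t1 = window
    if t1 <= t0:
        raise ConfigurationError("window must have positive length")
    if t0 < series.start_time - 1e-9 or t1 > series.end_time + 1e-9:
        raise DataError("window lies outside the series")
    mask = series.window_mask(t0, t1)
    vals = series.values[mask]
    if vals.size < min_bins or vals.size == 0:
        raise DataError(f"window holds {vals.size} bins, need at least {max(min_bins, 1)}")
    mean = float(vals.mean())
    if mean <= 0:
        raise DegenerateSeriesError("window mean must be positive")
    if extremum_mode == "single":
        vmax, vmin = float(vals.max()), float(vals.min())
    else:
        k = min(max(top_k, 1), vals.size)
        s = np.sort(vals)
        vmax, vmin = float(s[-k:].mean()), float(s[:k].mean())
    return BurstMetrics(
        window=(t0, t1),
        mean_rsna=mean,
        max_over_mean=vmax / mean,
        min_over_mean=vmin / mean,
        extremum_mode=extremum_mode,
        n_bins=int(vals.size),
    )
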