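"""Baroreflex curve construction and pharmacological reflex quantification.

The baroreflex sympathoinhibition curve plots RSNA (percent of control)
against per-beat mean blood pressure while pressure is swept downward by a
vasodilator bolus and upward by an alpha-agonist infusion. Per subject,
paired (MBP, RSNA%) beats are averaged in 5-mmHg pressure bins (anchored at
absolute multiples of 5 mmHg so bins are commensurable across subjects);
group curves average subject bin means. The descending limb's slope is an
ordinary least-squares fit over the 10-90% transition band, and the lower
plateau pressure is read as the lowest-pressure bin from which the curve
stays within a tolerance of its minimum -- an explicitly declared
operationalization, since 'plateau value' has no unique estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    ConfigurationError,
    DataError,
    InsufficientRangeError,
    NoPlateauError,
)
from .synthetic import InterventionSpec

__all__ = [
    "BaroreflexCurve",
    "SlopeEstimate",
    "ReflexResponse",
    "build_baroreflex_curve",
    "average_curves",
    "descending_slope",
    "plateau_pressure",
    "drug_response",
    "bezold_jarisch_response",
    "fit_logistic_curve",
]

BIN_MMHG = 5.0


@dataclass(frozen=True)
class BaroreflexCurve:
    """Per-5-mmHg-bin RSNA% curve, per subject or group-averaged."""

    bin_left: np.ndarray  # mmHg, left edges (multiples of bin_width)
    mean_pct: np.ndarray
    sem: np.ndarray
    n: np.ndarray  # pairs per bin (subject) or subjects per bin (group)
    bin_width: float = BIN_MMHG
    level: str = "subject"

    def __post_init__(self) -> None:
        order = np.argsort(self.bin_left)
        for name in ("bin_left", "mean_pct", "sem", "n"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float)[order])

    @property
    def n_bins(self) -> int:
        return self.bin_left.size

    @property
    def bin_centers(self) -> np.ndarray:
        return self.bin_left + self.bin_width / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low_mmHg": self.bin_left,
                "bin_high_mmHg": self.bin_left + self.bin_width,
                "mean_rsna_pct": self.mean_pct,
                "sem": self.sem,
                "n": self.n.astype(int),
            }
        )

    def plot(self, ax=None, **kwargs):
        """Errorbar plot of the curve (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.bin_centers, self.mean_pct, yerr=self.sem, marker="o", **kwargs)
        ax.set_xlabel("MBP (mmHg)")
        ax.set_ylabel("RSNA (% of control)")
        return ax


@dataclass(frozen=True)
class SlopeEstimate:
    slope: float  # % RSNA per mmHg (negative for sympathoinhibition)
    intercept: float
    fit_range: tuple[float, float]  # mmHg, centers of first/last fitted bin
    r_squared: float
    n_bins: int


@dataclass(frozen=True)
class ReflexResponse:
    agent: str
    baseline_mbp: float
    baseline_hr: float
    delta_mbp: float  # mmHg, signed
    delta_hr: float  # bpm, signed
    rsna_inhibition_pct: float  # signed; negative = inhibition; NaN if unmeasured
    time_of_extremum: float
    flags: tuple[str, ...] = field(default=())


def build_baroreflex_curve(
    mbp: np.ndarray,
    rsna_pct: np.ndarray,
    bin_width: float = BIN_MMHG,
    min_bins: int = 6,
) -> BaroreflexCurve:
    """Bin paired per-beat (MBP, RSNA%) samples into half-open pressure bins.

    Each pair lands in ``[floor(MBP/w)*w, floor(MBP/w)*w + w)``; a value on
    an edge belongs to the higher bin. Callers restrict the pairs to the
    reflex window (vasodilator nadir through the end of the pressor ramp).
    """
    mbp = np.asarray(mbp, dtype=float)
    rsna_pct = np.asarray(rsna_pct, dtype=float)
    if mbp.size != rsna_pct.size:
        raise DataError("mbp and rsna_pct must have equal length")
    if mbp.size == 0:
        raise DataError("no pairs to bin")
    if bin_width <= 0:
        raise ConfigurationError("bin_width must be positive")
    left = np.floor(mbp / bin_width) * bin_width
    uniq, inverse = np.unique(left, return_inverse=True)
    if uniq.size < min_bins:
        raise InsufficientRangeError(
            f"only {uniq.size} occupied pressure bins; need at least {min_bins}"
        )
    counts = np.bincount(inverse)
    sums = np.bincount(inverse, weights=rsna_pct)
    means = sums / counts
    sq = np.bincount(inverse, weights=rsna_pct**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (sq - counts * means**2) / np.maximum(counts - 1, 1)
        sem = np.sqrt(np.clip(var, 0.0, None) / counts)
    sem[counts < 2] = np.nan
    return BaroreflexCurve(uniq, means, sem, counts.astype(float), bin_width, level="subject")


def average_curves(curves: list[BaroreflexCurve], min_subjects: int = 2) -> BaroreflexCurve:
    """Group curve: unweighted mean of subject bin-means, SEM across subjects.

    Bins present in fewer than ``min_subjects`` subjects are dropped so
    group bins always summarize at least two animals.
    """
    if len(curves) < 2:
        raise DataError("need at least two subject curves to average")
    bw = curves[0].bin_width
    if any(abs(c.bin_width - bw) > 1e-9 for c in curves):
        raise DataError("curves must share the bin width")
    table: dict[float, list[float]] = {}
    for c in curves:
        for left, mean in zip(c.bin_left, c.mean_pct):
            table.setdefault(round(float(left), 6), []).append(float(mean))
    rows = [(left, vals) for left, vals in sorted(table.items()) if len(vals) >= min_subjects]
    if not rows:
        raise InsufficientRangeError("no pressure bin is shared by enough subjects")
    lefts = np.array([r[0] for r in rows])
    means = np.array([np.mean(r[1]) for r in rows])
    sems = np.array(
        [np.std(r[1], ddof=1) / np.sqrt(len(r[1])) if len(r[1]) > 1 else np.nan for r in rows]
    )
    ns = np.array([len(r[1]) for r in rows], dtype=float)
    return BaroreflexCurve(lefts, means, sems, ns, bw, level="group")


def descending_slope(
    curve: BaroreflexCurve,
    band: tuple[float, float] = (0.1, 0.9),
    min_bins: int = 4,
    min_transition_fraction: float = 0.2,
) -> SlopeEstimate:
    """OLS slope of the descending limb over the 10-90% transition band.

    Bins whose mean lies strictly between ``lower + band[0]*range`` and
    ``lower + band[1]*range`` of the curve's RSNA range are fitted; the
    curve must span a transition of at least ``min_transition_fraction`` of
    its top value.
    """
    y = curve.mean_pct
    top, bottom = float(y.max()), float(y.min())
    rng = top - bottom
    if rng < min_transition_fraction * abs(top) or rng <= 0:
        raise InsufficientRangeError("curve spans no usable sympathoinhibition transition")
    lo = bottom + band[0] * rng
    hi = bottom + band[1] * rng
    mask = (y > lo) & (y < hi)
    if mask.sum() < min_bins:
        raise InsufficientRangeError(
            f"only {int(mask.sum())} bins in the transition band; need {min_bins}"
        )
    x = curve.bin_centers[mask]
    res = stats.linregress(x, y[mask])
    return SlopeEstimate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_range=(float(x.min()), float(x.max())),
        r_squared=float(res.rvalue**2),
        n_bins=int(mask.sum()),
    )


def _median3(y: np.ndarray) -> np.ndarray:
    """3-point median filter; unbiased on monotone segments, endpoints kept."""
    if y.size < 3:
        return y.copy()
    out = y.copy()
    stacked = np.stack([y[:-2], y[1:-1], y[2:]])
    out[1:-1] = np.median(stacked, axis=0)
    return out


def plateau_pressure(curve: BaroreflexCurve, tol_pct: float = 5.0, min_run: int = 2) -> float:
    """Pressure (bin center, mmHg) where the curve enters its lower plateau.

    The plateau level (floor) is the median of the median-filtered curve
    over the bins in the top quartile of the pressure span; the plateau
    starts at the lowest-pressure bin from which every higher-pressure bin
    stays within ``tol_pct`` percent of the curve range above that floor.
    The flat run must span at least ``min_run`` bins and must be flat in
    rate: a run falling faster than the tolerance per four bins is a
    continuing descent, so a monotone curve raises :class:`NoPlateauError`.
    Bins supported by fewer than half as many samples/subjects as the
    best-supported bin are ignored (sweep extremes are erratic), and the
    floor is a robust location rather than the single lowest bin because
    with many plateau bins the minimum is biased low by sampling noise.
    This estimator is a declared stand-in -- report it alongside results.
    """
    if not 0 < tol_pct < 100:
        raise ConfigurationError("tol_pct must lie in (0, 100)")
    # drop sparsely supported bins (sweep extremes); threshold never exceeds
    # the best-supported bin so uniformly thin curves keep all bins
    thresh = min(max(2.0, 0.5 * float(np.median(curve.n))), float(curve.n.max()))
    support = curve.n >= thresh
    y = _median3(curve.mean_pct[support])
    centers = curve.bin_centers[support]
    if y.size < min_run:
        raise NoPlateauError("too few well-supported bins")
    span = float(centers[-1] - centers[0])
    n_floor = max(int(np.sum(centers >= centers[-1] - 0.25 * span)), min(3, y.size))
    floor = float(np.median(y[-n_floor:]))
    tol = tol_pct / 100.0 * float(y.max() - floor)
    if tol <= 0:  # flat curve: everything is plateau
        return float(centers[0])
    within = y <= floor + tol
    start = None
    for i in range(y.size - 1, -1, -1):
        if within[i]:
            start = i
        else:
            break
    if start is None or (y.size - start) < min_run:
        raise NoPlateauError("curve never flattens into a lower plateau")
    run_x, run_y = centers[start:], y[start:]
    if run_x[-1] > run_x[0]:
        res = stats.linregress(run_x, run_y)
        if abs(res.slope) > tol / (4.0 * curve.bin_width):
            raise NoPlateauError("terminal run keeps falling; no lower plateau")
    return float(centers[start])


def fit_logistic_curve(curve: BaroreflexCurve) -> dict:
    """Optional 4-parameter logistic cross-check fit of a baroreflex curve.

    Returns dict with upper, lower, p50 (mmHg), k (mmHg). Not used by the
    primary slope/plateau estimators; provided for comparison.
    """
    x, y = curve.bin_centers, curve.mean_pct

    def model(x, upper, lower, p50, k):
        return lower + (upper - lower) / (1.0 + np.exp((x - p50) / k))

    p0 = (float(y.max()), float(y.min()), float(np.median(x)), 5.0)
    bounds = ([0, 0, x.min() - 50, 0.5], [np.inf, np.inf, x.max() + 50, 100.0])
    popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds, maxfev=20000)
    return {"upper": popt[0], "lower": popt[1], "p50": popt[2], "k": popt[3]}


# ---------------------------------------------------------------------------
# Drug responses
# ---------------------------------------------------------------------------

#: default post-event search windows (s)
SEARCH_WINDOW_S = {"diltiazem": 120.0, "phenylephrine": 150.0, "cpbg": 60.0}
#: extremum direction of the pressure response per agent
_MBP_DIRECTION = {"diltiazem": -1.0, "phenylephrine": +1.0, "cpbg": -1.0}
#: extremum direction of the HR response (reflex tachycardia for the
#: vasodilator, baroreflex/vagal bradycardia otherwise)
_HR_DIRECTION = {"diltiazem": +1.0, "phenylephrine": -1.0, "cpbg": -1.0}


def _smooth_time(times: np.ndarray, values: np.ndarray, width_s: float) -> np.ndarray:
    """Centered moving average over a time window for irregular samples."""
    if width_s <= 0:
        return values
    half = width_s / 2.0
    cums = np.concatenate(([0.0], np.cumsum(values)))
    left = np.searchsorted(times, times - half, side="left")
    right = np.searchsorted(times, times + half, side="right")
    return (cums[right] - cums[left]) / np.maximum(right - left, 1)


def _extremum(times, values, mask, direction):
    v = values[mask]
    tt = times[mask]
    i = int(np.argmax(direction * v))
    return float(v[i]), float(tt[i])


def drug_response(
    times: np.ndarray,
    mbp: np.ndarray,
    hr: np.ndarray,
    event: InterventionSpec,
    baseline_s: float = 60.0,
    search_s: float | None = None,
    smooth_s: float = 5.0,
) -> ReflexResponse:
    """Baseline and peak-change hemodynamics for one intervention.

    Baseline is the mean over ``baseline_s`` before the event; the extremum
    (nadir for hypotensive agents, peak for the pressor) is taken on a
    ``smooth_s`` moving average within the post-event search window.
    """
    times = np.asarray(times, dtype=float)
    mbp = np.asarray(mbp, dtype=float)
    hr = np.asarray(hr, dtype=float)
    t0 = event.onset_time
    if search_s is None:
        search_s = SEARCH_WINDOW_S[event.agent]
    base_mask = (times >= t0 - baseline_s) & (times < t0)
    if not base_mask.any():
        raise DataError("no samples in the pre-event baseline window")
    search_mask = (times >= t0) & (times < t0 + search_s)
    if not search_mask.any():
        raise DataError("no samples in the post-event search window")
    baseline_mbp = float(mbp[base_mask].mean())
    baseline_hr = float(hr[base_mask].mean())
    mbp_s = _smooth_time(times, mbp, smooth_s)
    hr_s = _smooth_time(times, hr, smooth_s)
    ext_mbp, t_ext = _extremum(times, mbp_s, search_mask, _MBP_DIRECTION[event.agent])
    ext_hr, _ = _extremum(times, hr_s, search_mask, _HR_DIRECTION[event.agent])
    return ReflexResponse(
        agent=event.agent,
        baseline_mbp=baseline_mbp,
        baseline_hr=baseline_hr,
        delta_mbp=ext_mbp - baseline_mbp,
        delta_hr=ext_hr - baseline_hr,
        rsna_inhibition_pct=float("nan"),
        time_of_extremum=t_ext,
    )


def bezold_jarisch_response(
    times: np.ndarray,
    rsna_pct: np.ndarray,
    mbp: np.ndarray,
    hr: np.ndarray,
    event: InterventionSpec,
    baseline_s: float = 60.0,
    search_s: float | None = None,
    smooth_s: float = 5.0,
) -> ReflexResponse:
    """Quantify the cardiopulmonary-chemoreflex transient for a CPBG bolus.

    RSNA inhibition is the minimum smoothed RSNA% within the search window
    minus 100, so complete nerve silence reads -100 and a subject whose
    activity never drops below control is reported >= 0 and flagged
    'non_responder'.
    """
    hemo = drug_response(times, mbp, hr, event, baseline_s, search_s, smooth_s)
    times = np.asarray(times, dtype=float)
    rsna_pct = np.asarray(rsna_pct, dtype=float)
    if search_s is None:
        search_s = SEARCH_WINDOW_S["cpbg"]
    mask = (times >= event.onset_time) & (times < event.onset_time + search_s)
    smoothed = _smooth_time(times, rsna_pct, smooth_s)
    inhibition = float(smoothed[mask].min()) - 100.0
    t_min = float(times[mask][np.argmin(smoothed[mask])])
    flags = ("non_responder",) if inhibition >= 0 else ()
    return ReflexResponse(
        agent=event.agent,
        baseline_mbp=hemo.baseline_mbp,
        baseline_hr=hemo.baseline_hr,
        delta_mbp=hemo.delta_mbp,
        delta_hr=hemo.delta_hr,
        rsna_inhibition_pct=inhibition,
        time_of_extremum=t_min,
        flags=flags,
    )
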