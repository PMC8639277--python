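"""statsmodels-style entry point: fit the whole RSNA analysis to one record.

``RSNAModel`` wraps a :class:`~rsnalab.core.SubjectRecord` (simulated or
loaded from disk) and ``fit()`` runs the standard chain -- systolic peak
detection, per-beat MBP and instantaneous HR, rectification,
beat-triggered cumulation, residual-background correction, percent of
control, burst metrics, RSNA-HR coupling, and (when the record contains a
vasodilator + pressor protocol) the baroreflex curve with slope and
plateau estimates plus per-event reflex responses. The returned
``RSNAResults`` carries estimates, dispersions and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import baroreflex as brx
from . import bursts, cardiac, processing
from .core import (
    BeatSeries,
    DataError,
    InsufficientRangeError,
    IntegratedSeries,
    NoPlateauError,
    SubjectRecord,
)
from .synthetic import InterventionSpec

__all__ = ["RSNAModel", "RSNAResults"]


@dataclass
class RSNAResults:
    """Fitted per-subject quantities. ``summary()`` renders a text report."""

    subject_id: str
    group: str
    control_window: tuple[float, float]
    control_mbp: float
    control_hr: float
    mean_rsna_uvs: float  # control-window mean cumulated RSNA (uV*s / window)
    beats: BeatSeries
    per_beat_times: np.ndarray
    per_beat_mbp: np.ndarray
    per_beat_hr: np.ndarray
    per_beat_rsna_pct: np.ndarray
    integrated_100ms: IntegratedSeries
    burst: bursts.BurstMetrics | None
    coupling: cardiac.CouplingResult | None
    curve: brx.BaroreflexCurve | None
    slope: brx.SlopeEstimate | None
    plateau_mmhg: float | None
    responses: list[brx.ReflexResponse]
    settings: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"RSNA analysis -- subject {self.subject_id} (group {self.group})",
            "=" * 60,
            f"control window        : {self.control_window[0]:.0f}-{self.control_window[1]:.0f} s",
            f"control MBP           : {self.control_mbp:.1f} mmHg",
            f"control HR            : {self.control_hr:.1f} bpm",
            f"control RSNA          : {self.mean_rsna_uvs:.4f} uV*s per "
            f"{self.settings.get('trigger_window_s', 0.5):.1f} s window (=100%)",
        ]
        if self.burst is not None:
            lines += [
                f"burst max/mean        : {self.burst.max_over_mean:.2f}",
                f"burst min/mean        : {self.burst.min_over_mean:.2f}",
            ]
        if self.coupling is not None:
            lines += [
                f"RSNA-HR correlation   : r={self.coupling.r:+.2f} at lag "
                f"{self.coupling.best_lag:+d} beats -> {self.coupling.classification} "
                f"(|r|>={self.coupling.threshold} criterion)",
            ]
        if self.slope is not None:
            lines.append(
                f"baroreflex slope      : {self.slope.slope:+.2f} %/mmHg "
                f"(r2={self.slope.r_squared:.3f}, {self.slope.n_bins} bins)"
            )
        if self.plateau_mmhg is not None:
            lines.append(f"plateau pressure      : {self.plateau_mmhg:.1f} mmHg")
        for r in self.responses:
            extra = ""
            if np.isfinite(r.rsna_inhibition_pct):
                extra = f", RSNA {r.rsna_inhibition_pct:+.0f}%"
            if r.flags:
                extra += f" [{','.join(r.flags)}]"
            lines.append(
                f"{r.agent:<14}: dMBP {r.delta_mbp:+.0f} mmHg, dHR {r.delta_hr:+.0f} bpm{extra}"
            )
        return "\n".join(lines)


class RSNAModel:
    """Analysis model for one subject recording.

    Parameters
    ----------
    record
        Pressure + raw RSNA channels with event markers.
    trigger_window_s
        Beat-triggered cumulation window (0.5 s default; 0.4 s matches the
        online display convention).
    control_s
        Control-window length ending at the first intervention (or taken
        from the start of an undisturbed recording).
    coupling_threshold, max_lag_beats
        RSNA-HR classifier settings.
    """

    def __init__(
        self,
        record: SubjectRecord,
        trigger_window_s: float = 0.5,
        control_s: float = 60.0,
        burst_bin_s: float = 0.1,
        burst_window_s: float = 60.0,
        coupling_threshold: float = 0.3,
        max_lag_beats: int = 10,
        plateau_tol_pct: float = 5.0,
        dc_window_s: float = 1.0,
    ) -> None:
        self.record = record
        self.trigger_window_s = trigger_window_s
        self.control_s = control_s
        self.burst_bin_s = burst_bin_s
        self.burst_window_s = burst_window_s
        self.coupling_threshold = coupling_threshold
        self.max_lag_beats = max_lag_beats
        self.plateau_tol_pct = plateau_tol_pct
        self.dc_window_s = dc_window_s

    @classmethod
    def from_record(cls, record: SubjectRecord, **kwargs) -> "RSNAModel":
        return cls(record, **kwargs)

    # -- helpers -----------------------------------------------------------

    def _control_window(self) -> tuple[float, float]:
        t_first = self.record.first_event_time()
        end = self.record.pressure.end_time if t_first is None else t_first
        start = max(end - self.control_s, self.record.pressure.start_time)
        if end - start < min(self.control_s, 30.0):
            raise DataError("recording too short for a control window")
        return (start, end)

    def _events(self) -> list[InterventionSpec]:
        evs = []
        for _, row in self.record.events.iterrows():
            evs.append(
                InterventionSpec(
                    agent=str(row["agent"]),
                    onset_time=float(row["time_s"]),
                    dose=float(row["dose"]),
                    dose_units=str(row["dose_units"]),
                )
            )
        return evs

    # -- fitting -----------------------------------------------------------

    def fit(self) -> RSNAResults:
        rec = self.record
        beats = cardiac.detect_systolic_peaks(rec.pressure)
        mbp_b = cardiac.mean_bp(rec.pressure, beats)
        hr = beats.hr_inst  # aligned with mbp_b (one value per interval)

        rect = processing.rectify(rec.rsna_raw, dc_window_s=self.dc_window_s)
        per_beat = cardiac.triggered_cumulation(rect, beats, self.trigger_window_s)
        # align per-beat arrays on the beats that have both a window and an IBI
        n = min(per_beat.values.size, mbp_b.values.size)
        times = per_beat.times[:n]
        rsna_raw_vals = per_beat.values[:n]
        mbp_vals = mbp_b.values[:n]
        hr_vals = hr[:n]

        # residual electrical background, expressed per trigger window
        rsna_corr = np.clip(
            rsna_raw_vals - rec.background_uv * self.trigger_window_s, 0.0, None
        )

        control = self._control_window()
        ctrl_mask = (times >= control[0]) & (times < control[1])
        if not ctrl_mask.any():
            raise DataError("no beats in the control window")
        mean_rsna = float(rsna_corr[ctrl_mask].mean())
        rsna_pct = processing.percent_of_control_values(
            rsna_corr, times, control, min_control_s=min(30.0, self.control_s)
        )
        control_mbp = float(mbp_vals[ctrl_mask].mean())
        control_hr = float(hr_vals[ctrl_mask].mean())

        # 100-ms integrated series and burst metrics over the control window
        series100 = processing.integrate_bins(rect, self.burst_bin_s)
        series100 = processing.subtract_background(series100, rec.background_uv)
        burst_window = (max(control[1] - self.burst_window_s, control[0]), control[1])
        try:
            burst = bursts.burst_stats(series100, burst_window)
        except DataError:
            burst = None

        # RSNA-HR coupling over the undisturbed (pre-event) portion
        t_first = rec.first_event_time()
        basal_end = rec.pressure.end_time if t_first is None else t_first
        basal_mask = times < basal_end
        coupling = None
        try:
            coupling = cardiac.rsna_hr_correlation(
                rsna_corr[basal_mask],
                hr_vals[basal_mask],
                max_lag_beats=self.max_lag_beats,
                threshold=self.coupling_threshold,
            )
        except DataError:
            pass

        events = self._events()
        curve = slope = plateau = None
        responses: list[brx.ReflexResponse] = []
        dilt = [e for e in events if e.agent == "diltiazem"]
        phe = [e for e in events if e.agent == "phenylephrine"]
        if dilt and phe:
            window_mask = times >= dilt[0].onset_time
            try:
                curve = brx.build_baroreflex_curve(
                    mbp_vals[window_mask], rsna_pct[window_mask]
                )
                slope = brx.descending_slope(curve)
            except InsufficientRangeError:
                pass
            if curve is not None:
                try:
                    plateau = brx.plateau_pressure(curve, tol_pct=self.plateau_tol_pct)
                except NoPlateauError:
                    plateau = None
        for ev in events:
            if ev.agent == "cpbg":
                responses.append(
                    brx.bezold_jarisch_response(times, rsna_pct, mbp_vals, hr_vals, ev)
                )
            else:
                responses.append(brx.drug_response(times, mbp_vals, hr_vals, ev))
        return RSNAResults(
            subject_id=rec.subject_id,
            group=rec.group,
            control_window=control,
            control_mbp=control_mbp,
            control_hr=control_hr,
            mean_rsna_uvs=mean_rsna,
            beats=beats,
            per_beat_times=times,
            per_beat_mbp=mbp_vals,
            per_beat_hr=hr_vals,
            per_beat_rsna_pct=rsna_pct,
            integrated_100ms=series100,
            burst=burst,
            coupling=coupling,
            curve=curve,
            slope=slope,
            plateau_mmhg=plateau,
            responses=responses,
            settings={
                "trigger_window_s": self.trigger_window_s,
                "control_s": self.control_s,
                "coupling_threshold": self.coupling_threshold,
                "max_lag_beats": self.max_lag_beats,
                "plateau_tol_pct": self.plateau_tol_pct,
                "coupling_note": (
                    "RSNA-HR classification uses a lagged Pearson correlation "
                    "threshold; a declared stand-in for visual assessment"
                ),
                "plateau_note": (
                    "plateau = lowest-pressure bin from which the curve stays "
                    "within tol of its minimum; a declared stand-in"
                ),
            },
        )
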