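"""Synthetic rat cohort generator: pressure waveforms, cardiac-locked RSNA
bursting and pharmacological intervention kernels for three phenotypes --
normotensive WKY, spontaneously hypertensive SHR, and SHR under chronic
low-dose L-NAME (SHRLN, severe hypertension with blunted baroreflex).

The generator exists so the full analysis pipeline can be exercised and
validated without animal data. Its phenomenology:

* arterial pressure = slowly varying mean blood pressure (basal level +
  intervention kernels + Ornstein-Uhlenbeck wander) plus a periodic
  intra-beat pulse of configurable pulse pressure;
* instantaneous heart period follows the (delayed) mean pressure through a
  linear baroreflex gain, with a weaker response to hypotension
  (chronotropic saturation under anesthesia) and a direct vagal kernel for
  the Bezold-Jarisch agonist;
* per-beat burst amplitude follows an inverse logistic of delayed mean
  pressure (the sympathoinhibition sigmoid); bursts are raised-cosine
  envelopes phase-locked to systole under a band-limited noise carrier,
  riding on a tonic (non-bursting) activity level plus a constant residual
  electrical background;
* ``coupling_jitter`` in [0, 1] degrades cardiac coupling: it jitters burst
  onset within the cycle and, because a multi-cycle cumulation window is
  insensitive to timing alone, it also replaces the wander component seen
  by the amplitude sigmoid with an independent surrogate wander.
  Deterministic intervention kernels remain coupled, so pharmacological
  baroreflex sweeps survive even in fully decoupled subjects.

All waveform parameters that the underlying physiology does not pin down
(burst shape and duration, wander scale, carrier band) are free generator
choices; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, lfilter, sosfiltfilt

from .core import (
    AlignmentError,
    BeatSeries,
    ConfigurationError,
    SubjectRecord,
    Trace,
)

__all__ = [
    "GroupPreset",
    "InterventionSpec",
    "SimulationConfig",
    "PressureSimulation",
    "WKY",
    "SHR",
    "SHRLN",
    "PRESETS",
    "baroreflex_sigmoid",
    "simulate_pressure",
    "simulate_rsna",
    "generate_subject",
    "generate_cohort",
    "standard_protocol",
]

GROUPS = ("WKY", "SHR", "SHRLN")

#: Fraction of the cardiac cycle occupied by the systolic pulse shape.
_PULSE_FRACTION = 0.6
#: Phase (fraction of the cycle) of the systolic maximum.
_PULSE_PEAK_PHASE = 0.3
#: Burst envelope duration (s) and onset latency after the systolic peak
#: (bursts are diastolic: they follow the systole within the same cycle).
_BURST_DURATION_S = 0.08
_BURST_LATENCY_S = 0.02


@dataclass(frozen=True)
class GroupPreset:
    """Phenotype parameters for one experimental group.

    Sigmoid parameters are in 'activity percent' units (an arbitrary
    per-subject scale; analyses normalize to percent of control);
    ``rsna_scale_uv_per_pct`` converts them to microvolts of burst envelope.
    """

    group_label: str
    basal_mbp: float  # mmHg, resting mean blood pressure
    basal_hr: float  # bpm
    pulse_pressure: float  # mmHg, per-beat systolic-diastolic excursion
    sigmoid_upper: float  # % upper RSNA plateau (full disinhibition)
    sigmoid_lower: float  # % lower RSNA plateau (full sympathoinhibition)
    sigmoid_p50: float  # mmHg, pressure of half-maximal sympathoinhibition
    sigmoid_k: float  # mmHg, steepness scale (larger = flatter reflex)
    coupling_jitter: float  # [0, 1]; 0 = phase-locked bursts, 1 = decoupled
    hr_baroreflex_gain: float  # bpm/mmHg (negative: pressure rise slows HR)
    background_uv: float  # uV, residual electrical offset (post-blockade)
    noise_sd_uv: float  # uV, per-beat burst-amplitude noise
    tonic_uv: float  # uV, non-bursting (tonic) nerve activity level
    rsna_scale_uv_per_pct: float = 0.05  # uV per sigmoid percent
    mbp_wander_sd: float = 2.0  # mmHg, OU wander standard deviation
    mbp_wander_tau: float = 2.0  # s, OU wander correlation time
    hr_hypotension_attenuation: float = 0.15  # gain fraction below basal MBP

    def __post_init__(self) -> None:
        if not self.sigmoid_upper > self.sigmoid_lower >= 0:
            raise ConfigurationError("require sigmoid_upper > sigmoid_lower >= 0")
        if not self.sigmoid_k > 0:
            raise ConfigurationError("sigmoid_k must be positive")
        if not 0 <= self.coupling_jitter <= 1:
            raise ConfigurationError("coupling_jitter must lie in [0, 1]")
        for name in ("basal_mbp", "basal_hr", "rsna_scale_uv_per_pct"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("pulse_pressure", "background_uv", "noise_sd_uv", "tonic_uv",
                     "mbp_wander_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


# Default presets. Basal MBP/HR anchor the post-surgery control state of
# each phenotype (WKY < SHR < SHRLN pressure ordering); sigmoid half-points
# mirror the rightward displacement of sympathoinhibition with severity,
# with SHRLN flattened (larger k, smaller range) and largely decoupled from
# the cardiac cycle. These are calibration anchors, not ground truth.
WKY = GroupPreset(
    group_label="WKY", basal_mbp=126.0, basal_hr=437.0, pulse_pressure=40.0,
    sigmoid_upper=120.0, sigmoid_lower=5.0, sigmoid_p50=110.0, sigmoid_k=8.0,
    coupling_jitter=0.05, hr_baroreflex_gain=-1.55,
    background_uv=0.05, noise_sd_uv=0.15, tonic_uv=0.10,
    rsna_scale_uv_per_pct=0.05,
)
SHR = GroupPreset(
    group_label="SHR", basal_mbp=142.0, basal_hr=374.0, pulse_pressure=50.0,
    sigmoid_upper=90.0, sigmoid_lower=6.0, sigmoid_p50=113.0, sigmoid_k=7.0,
    coupling_jitter=0.10, hr_baroreflex_gain=-1.16,
    background_uv=0.03, noise_sd_uv=0.15, tonic_uv=0.35,
    rsna_scale_uv_per_pct=0.04,
)
SHRLN = GroupPreset(
    group_label="SHRLN", basal_mbp=156.0, basal_hr=355.0, pulse_pressure=55.0,
    sigmoid_upper=60.0, sigmoid_lower=8.0, sigmoid_p50=135.0, sigmoid_k=10.0,
    coupling_jitter=0.85, hr_baroreflex_gain=-0.32,
    background_uv=0.03, noise_sd_uv=0.12, tonic_uv=0.60,
    rsna_scale_uv_per_pct=0.025,
)
PRESETS: dict[str, GroupPreset] = {"WKY": WKY, "SHR": SHR, "SHRLN": SHRLN}


def baroreflex_sigmoid(mbp, preset: GroupPreset):
    """Inverse logistic mapping (delayed) MBP to burst amplitude (percent)."""
    mbp = np.asarray(mbp, dtype=float)
    z = (mbp - preset.sigmoid_p50) / preset.sigmoid_k
    return preset.sigmoid_lower + (preset.sigmoid_upper - preset.sigmoid_lower) / (
        1.0 + np.exp(z)
    )


# ---------------------------------------------------------------------------
# Interventions
# ---------------------------------------------------------------------------

AGENTS = ("diltiazem", "phenylephrine", "cpbg")

# Hypotensive magnitude of the calcium blocker bolus and ceiling of the
# alpha-agonist infusion ramp, per phenotype (mmHg).
_DILTIAZEM_MAGNITUDE = {"WKY": 77.0, "SHR": 89.0, "SHRLN": 96.0}
_PHENYLEPHRINE_CEILING = {"WKY": 69.0, "SHR": 79.0, "SHRLN": 81.0}

# Dose-response anchors for the 5-HT3 agonist bolus (dose in ug/kg):
# transient sympathoinhibition depth (fraction), hypotension (mmHg) and
# bradycardia (bpm); intermediate doses interpolate on log dose.
_CPBG_DOSES = np.array([1.0, 3.0, 20.0])
_CPBG_DEPTH = np.array([0.60, 0.70, 0.78])
_CPBG_MBP_DROP = np.array([19.0, 30.0, 49.0])
_CPBG_HR_DROP = np.array([49.0, 107.0, 257.0])


def _cpbg_dose_interp(dose: float, table: np.ndarray) -> float:
    return float(np.interp(math.log(max(dose, 1e-6)), np.log(_CPBG_DOSES), table))


def default_kinetics(agent: str, dose: float, group: str | None = None) -> dict:
    """Default phenomenological kernel parameters for one intervention."""
    if agent == "diltiazem":
        return {
            "magnitude_mmhg": _DILTIAZEM_MAGNITUDE.get(group or "", 77.0),
            "time_to_nadir_s": 30.0,
            "recovery_tau_s": 45.0,
        }
    if agent == "phenylephrine":
        return {
            "ramp_mmhg_per_s": 1.0,
            "ceiling_mmhg": _PHENYLEPHRINE_CEILING.get(group or "", 69.0),
        }
    if agent == "cpbg":
        return {
            "inhibition_depth": _cpbg_dose_interp(dose, _CPBG_DEPTH),
            "mbp_drop_mmhg": _cpbg_dose_interp(dose, _CPBG_MBP_DROP),
            "hr_drop_bpm": _cpbg_dose_interp(dose, _CPBG_HR_DROP),
            "onset_tau_s": 0.2,
            "hold_s": 8.0,
            "recovery_tau_s": 30.0,
        }
    raise ConfigurationError(f"unknown agent {agent!r}")


@dataclass(frozen=True)
class InterventionSpec:
    """One drug administration and its phenomenological kernel."""

    agent: str
    onset_time: float  # s
    dose: float
    dose_units: str = ""
    kinetics: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.agent not in AGENTS:
            raise ConfigurationError(f"agent must be one of {AGENTS}")
        if self.onset_time < 0:
            raise ConfigurationError("onset_time must be >= 0")

    def resolved_kinetics(self, group: str | None = None) -> dict:
        kin = default_kinetics(self.agent, self.dose, group)
        kin.update(self.kinetics)
        return kin


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to generate one subject's recording."""

    preset: GroupPreset
    protocol: tuple[InterventionSpec, ...] = ()
    duration: float = 180.0
    sampling_rate: float = 1000.0
    baroreflex_delay: float = 0.3  # s, afferent-to-efferent latency
    seed: int = 0
    carrier: str = "noise"  # 'noise' or 'deterministic'
    min_control_s: float = 60.0

    def __post_init__(self) -> None:
        if self.sampling_rate < 500.0:
            raise ConfigurationError(
                "sampling_rate must be >= 500 Hz to resolve the rat cardiac cycle"
            )
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if self.baroreflex_delay < 0:
            raise ConfigurationError("baroreflex_delay must be >= 0")
        if self.carrier not in ("noise", "deterministic"):
            raise ConfigurationError("carrier must be 'noise' or 'deterministic'")
        protocol = tuple(sorted(self.protocol, key=lambda e: e.onset_time))
        object.__setattr__(self, "protocol", protocol)
        if protocol:
            first, last = protocol[0].onset_time, protocol[-1].onset_time
            if first < self.min_control_s:
                raise ConfigurationError(
                    f"first intervention at {first:g} s leaves less than the "
                    f"{self.min_control_s:g} s control window"
                )
            if last >= self.duration:
                raise ConfigurationError("intervention onset beyond recording end")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-purpose random stream derived from the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        )


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------


def _diltiazem_shape(t: np.ndarray, onset: float, t_nadir: float, tau_rec: float) -> np.ndarray:
    u = t - onset
    tau_on = t_nadir / 3.5
    peak = 1.0 - math.exp(-3.5)
    shape = np.zeros_like(t)
    rising = (u >= 0) & (u <= t_nadir)
    shape[rising] = 1.0 - np.exp(-u[rising] / tau_on)
    after = u > t_nadir
    shape[after] = peak * np.exp(-(u[after] - t_nadir) / tau_rec)
    return shape


def _cpbg_shape(t: np.ndarray, onset: float, tau_on: float, hold: float, tau_rec: float) -> np.ndarray:
    u = t - onset
    shape = np.zeros_like(t)
    rising = (u >= 0) & (u <= hold)
    shape[rising] = 1.0 - np.exp(-u[rising] / tau_on)
    lvl = 1.0 - math.exp(-hold / tau_on)
    after = u > hold
    shape[after] = lvl * np.exp(-(u[after] - hold) / tau_rec)
    return shape


def _mbp_offset(t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Summed intervention effect on mean blood pressure (mmHg)."""
    group = config.preset.group_label
    total = np.zeros_like(t)
    for ev in config.protocol:
        kin = ev.resolved_kinetics(group)
        if ev.agent == "diltiazem":
            total -= kin["magnitude_mmhg"] * _diltiazem_shape(
                t, ev.onset_time, kin["time_to_nadir_s"], kin["recovery_tau_s"]
            )
        elif ev.agent == "phenylephrine":
            total += np.clip(
                kin["ramp_mmhg_per_s"] * (t - ev.onset_time), 0.0, kin["ceiling_mmhg"]
            )
        elif ev.agent == "cpbg":
            total -= kin["mbp_drop_mmhg"] * _cpbg_shape(
                t, ev.onset_time, kin["onset_tau_s"], kin["hold_s"], kin["recovery_tau_s"]
            )
    return total


def _hr_offset(t: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Direct (vagal) chronotropic kernels, currently the CPBG bolus only."""
    group = config.preset.group_label
    total = np.zeros_like(t)
    for ev in config.protocol:
        if ev.agent != "cpbg":
            continue
        kin = ev.resolved_kinetics(group)
        total -= kin["hr_drop_bpm"] * _cpbg_shape(
            t, ev.onset_time, kin["onset_tau_s"], kin["hold_s"], kin["recovery_tau_s"]
        )
    return total


def _inhibition_events(t: np.ndarray, config: SimulationConfig) -> list[tuple[float, np.ndarray]]:
    """(depth, shape(t)) per CPBG event; shape peaks at 1 during the hold."""
    group = config.preset.group_label
    out = []
    for ev in config.protocol:
        if ev.agent != "cpbg":
            continue
        kin = ev.resolved_kinetics(group)
        shape = _cpbg_shape(
            t, ev.onset_time, kin["onset_tau_s"], kin["hold_s"], kin["recovery_tau_s"]
        )
        peak = float(shape.max(initial=0.0))
        if peak > 0:
            shape = shape / max(peak, 1.0)  # hold plateau already ~1
        out.append((float(kin["inhibition_depth"]), shape))
    return out


def _ou_process(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path (exact discretization)."""
    if sd <= 0 or n == 0:
        return np.zeros(n)
    a = math.exp(-dt / tau)
    innov = rng.standard_normal(n) * (sd * math.sqrt(1.0 - a * a))
    innov[0] = rng.standard_normal() * sd
    x, _ = lfilter([1.0], [1.0, -a], innov, zi=[0.0])
    return x


# ---------------------------------------------------------------------------
# Pressure simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PressureSimulation:
    """Pressure trace plus generator internals needed downstream.

    ``beats`` carries ground-truth systolic peak times for validation;
    analyses must detect their own peaks from ``pressure``.
    """

    config: SimulationConfig
    pressure: Trace
    beats: BeatSeries
    beat_starts: np.ndarray
    beat_ibis: np.ndarray
    mbp: np.ndarray  # full MBP trajectory (kernels + wander)
    mbp_drive: np.ndarray  # deterministic part (basal + kernels)
    wander: np.ndarray
    surrogate_wander: np.ndarray
    hr_kernel: np.ndarray


def simulate_pressure(config: SimulationConfig) -> PressureSimulation:
    """Generate the arterial pressure channel and ground-truth beat times."""
    p = config.preset
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    mbp_drive = p.basal_mbp + _mbp_offset(t, config)
    hr_kernel = _hr_offset(t, config)
    wander = _ou_process(n, 1.0 / fs, p.mbp_wander_sd, p.mbp_wander_tau, config.rng(0))
    surrogate = _ou_process(n, 1.0 / fs, p.mbp_wander_sd, p.mbp_wander_tau, config.rng(1))
    mbp = mbp_drive + wander
    if float(mbp.min()) <= 0:
        raise ConfigurationError("configuration drives MBP to non-positive values")

    d = int(round(config.baroreflex_delay * fs))
    if d > 0:
        mbp_delayed = np.concatenate((np.full(d, mbp[0]), mbp[: n - d]))
    else:
        mbp_delayed = mbp

    starts: list[float] = []
    ibis: list[float] = []
    s = 0.0
    while s < config.duration:
        i = min(int(s * fs), n - 1)
        dm = mbp_delayed[i] - p.basal_mbp
        gain = p.hr_baroreflex_gain * (1.0 if dm > 0 else p.hr_hypotension_attenuation)
        hr = p.basal_hr + gain * dm + hr_kernel[i]
        hr = min(max(hr, 120.0), 650.0)
        ibi = 60.0 / hr
        starts.append(s)
        ibis.append(ibi)
        s += ibi
    beat_starts = np.asarray(starts)
    beat_ibis = np.asarray(ibis)

    idx = np.searchsorted(beat_starts, t, side="right") - 1
    phi = (t - beat_starts[idx]) / beat_ibis[idx]
    pulse = np.where(
        phi < _PULSE_FRACTION,
        np.sin(np.pi * np.minimum(phi, _PULSE_FRACTION) / _PULSE_FRACTION) ** 2,
        0.0,
    )
    pulse_mean = _PULSE_FRACTION / 2.0
    values = mbp + p.pulse_pressure * (pulse - pulse_mean)
    pressure = Trace(values, fs, unit="mmHg")

    peak_times = beat_starts + _PULSE_PEAK_PHASE * beat_ibis
    peak_times = peak_times[peak_times < config.duration - 1.0 / fs]
    beats = BeatSeries(peak_times)
    return PressureSimulation(
        config=config,
        pressure=pressure,
        beats=beats,
        beat_starts=beat_starts,
        beat_ibis=beat_ibis,
        mbp=mbp,
        mbp_drive=mbp_drive,
        wander=wander,
        surrogate_wander=surrogate,
        hr_kernel=hr_kernel,
    )


# ---------------------------------------------------------------------------
# RSNA simulation
# ---------------------------------------------------------------------------


def _carrier(n: int, fs: float, rng: np.random.Generator, mode: str) -> np.ndarray:
    """Zero-mean carrier with unit mean absolute value.

    'noise': band-limited Gaussian noise (30 Hz to 1 kHz or the usable band
    below Nyquist), the multiunit-signal stand-in. 'deterministic': an
    alternating +-1 square carrier whose rectification is exactly the
    envelope -- used for analytic checks.
    """
    if mode == "deterministic":
        c = np.ones(n)
        c[1::2] = -1.0
        return c
    w = rng.standard_normal(n)
    hi = min(1000.0, 0.45 * fs)
    if hi > 35.0:
        sos = butter(4, [30.0, hi], btype="bandpass", fs=fs, output="sos")
    else:
        sos = butter(4, 30.0, btype="highpass", fs=fs, output="sos")
    c = sosfiltfilt(sos, w)
    return c / np.mean(np.abs(c))


def simulate_rsna(config: SimulationConfig, psim: PressureSimulation) -> Trace:
    """Generate the raw bipolar nerve channel for a simulated pressure run."""
    if psim.config is not config and psim.config != config:
        raise AlignmentError("pressure simulation was produced by a different config")
    p = config.preset
    fs = config.sampling_rate
    n = psim.pressure.n
    t = np.arange(n) / fs
    j = p.coupling_jitter

    # Pressure input to the amplitude sigmoid: the deterministic trajectory
    # stays coupled; the wander component is mixed with an independent
    # surrogate in proportion to the decoupling parameter.
    mbp_eff = psim.mbp_drive + (1.0 - j) * psim.wander + j * psim.surrogate_wander
    d = int(round(config.baroreflex_delay * fs))
    if d > 0:
        mbp_eff = np.concatenate((np.full(d, mbp_eff[0]), mbp_eff[: n - d]))

    starts, ibis = psim.beat_starts, psim.beat_ibis
    peak_times = starts + _PULSE_PEAK_PHASE * ibis
    pk_idx = np.clip(np.round(peak_times * fs).astype(int), 0, n - 1)
    amp_pct = baroreflex_sigmoid(mbp_eff[pk_idx], p)

    # Central sympathoinhibition (Bezold-Jarisch agonist): burst amplitude is
    # pinned toward (1 - depth) x basal level during the transient, so the
    # reflex silences the nerve regardless of the concurrent hypotension.
    inhibitions = _inhibition_events(t, config)
    sig_basal = float(baroreflex_sigmoid(p.basal_mbp, p))
    tonic = np.full(n, p.tonic_uv)
    for depth, shape in inhibitions:
        s_at_peaks = shape[pk_idx]
        amp_pct = (1.0 - s_at_peaks) * amp_pct + s_at_peaks * (1.0 - depth) * sig_basal
        tonic = (1.0 - shape * depth) * tonic

    amp_uv = p.rsna_scale_uv_per_pct * amp_pct
    if p.noise_sd_uv > 0:
        amp_uv = amp_uv + config.rng(2).normal(0.0, p.noise_sd_uv, amp_uv.size)
    amp_uv = np.clip(amp_uv, 0.0, None)

    onsets = peak_times + _BURST_LATENCY_S
    if j > 0:
        onsets = onsets + j * config.rng(3).uniform(-0.45, 0.45, onsets.size) * ibis

    m = max(int(round(_BURST_DURATION_S * fs)), 2)
    shape = 0.5 * (1.0 - np.cos(2.0 * np.pi * (np.arange(m) + 0.5) / m))
    start_idx = np.round(onsets * fs).astype(int)
    keep = (start_idx >= 0) & (start_idx + m <= n)
    envelope = tonic
    if keep.any():
        flat_idx = (start_idx[keep, None] + np.arange(m)[None, :]).ravel()
        contrib = (amp_uv[keep, None] * shape[None, :]).ravel()
        np.add.at(envelope, flat_idx, contrib)

    carrier = _carrier(n, fs, config.rng(4), config.carrier)
    raw = (envelope + p.background_uv) * carrier
    return Trace(raw, fs, unit="uV")


# ---------------------------------------------------------------------------
# Subjects, protocols, cohorts
# ---------------------------------------------------------------------------


def standard_protocol(
    preset: GroupPreset,
    kind: str,
    cpbg_doses: Sequence[float] = (1.0, 3.0, 20.0),
) -> tuple[tuple[InterventionSpec, ...], float]:
    """Standard intervention protocols and their recording durations.

    'basal': 180 s undisturbed recording.
    'baroreflex': calcium-blocker bolus at 60 s (hypotension), alpha-agonist
    infusion from 150 s ramping to the phenotype ceiling, held 30 s.
    'cpbg': 5-HT3 agonist boluses 150 s apart after a 60 s control window.
    """
    if kind == "basal":
        return (), 180.0
    if kind == "baroreflex":
        dilt = InterventionSpec("diltiazem", 60.0, 1.0, "mg/kg")
        phe = InterventionSpec("phenylephrine", 150.0, 20.0, "ug/kg/min")
        ceiling = _PHENYLEPHRINE_CEILING[preset.group_label]
        duration = 150.0 + ceiling / 1.0 + 30.0
        return (dilt, phe), duration
    if kind == "cpbg":
        events = tuple(
            InterventionSpec("cpbg", 60.0 + i * 150.0, float(dose), "ug/kg")
            for i, dose in enumerate(cpbg_doses)
        )
        return events, events[-1].onset_time + 120.0
    raise ConfigurationError(f"unknown protocol kind {kind!r}")


def generate_subject(
    preset: GroupPreset,
    protocol: Iterable[InterventionSpec],
    seed: int,
    duration: float | None = None,
    sampling_rate: float = 1000.0,
    subject_id: str | None = None,
    carrier: str = "noise",
    baroreflex_delay: float = 0.3,
) -> SubjectRecord:
    """Compose the two simulators into one SubjectRecord.

    Ground truth (preset, beat times, seed) goes in ``record.truth`` and is
    never consumed by the analysis pipeline.
    """
    protocol = tuple(protocol)
    if duration is None:
        ends = [60.0]
        for ev in protocol:
            kin = ev.resolved_kinetics(preset.group_label)
            if ev.agent == "phenylephrine":
                ends.append(ev.onset_time + kin["ceiling_mmhg"] / kin["ramp_mmhg_per_s"] + 30.0)
            else:
                ends.append(ev.onset_time + 120.0)
        duration = max(ends) + 60.0 if not protocol else max(ends)
        duration = max(duration, 180.0)
    config = SimulationConfig(
        preset=preset,
        protocol=protocol,
        duration=float(duration),
        sampling_rate=sampling_rate,
        baroreflex_delay=baroreflex_delay,
        seed=int(seed),
        carrier=carrier,
    )
    psim = simulate_pressure(config)
    rsna = simulate_rsna(config, psim)
    events = pd.DataFrame(
        {
            "time_s": [ev.onset_time for ev in config.protocol],
            "agent": [ev.agent for ev in config.protocol],
            "dose": [ev.dose for ev in config.protocol],
            "dose_units": [ev.dose_units for ev in config.protocol],
        }
    )
    truth = {
        "preset": asdict(preset),
        "seed": int(seed),
        "beat_times": psim.beats.peak_times.tolist(),
        "baroreflex_delay": config.baroreflex_delay,
        "kinetics": [ev.resolved_kinetics(preset.group_label) for ev in config.protocol],
    }
    return SubjectRecord(
        subject_id=subject_id or f"{preset.group_label}-{seed}",
        group=preset.group_label,
        pressure=psim.pressure,
        rsna_raw=rsna,
        events=events,
        background_uv=preset.background_uv,
        truth=truth,
        meta={
            "sampling_rate": sampling_rate,
            "duration": config.duration,
            "seed": int(seed),
            "carrier": carrier,
        },
    )


def generate_cohort(
    n_per_group: Mapping[str, int],
    seed: int,
    protocol_kind: str = "baroreflex",
    presets: Mapping[str, GroupPreset] | None = None,
    sampling_rate: float = 1000.0,
    duration: float | None = None,
) -> list[SubjectRecord]:
    """Generate a multi-group cohort with per-subject seeds derived from one
    master seed (counter-based, so cohorts are reproducible bit-for-bit)."""
    presets = dict(presets or PRESETS)
    total = 0
    for group, count in n_per_group.items():
        if count < 1:
            raise ConfigurationError("group counts must be >= 1")
        if group not in presets:
            raise ConfigurationError(f"no preset for group {group!r}")
        total += count
    sub_seeds = np.random.default_rng(int(seed)).integers(0, 2**31 - 1, size=total)
    records: list[SubjectRecord] = []
    k = 0
    for group, count in n_per_group.items():
        preset = presets[group]
        protocol, proto_duration = standard_protocol(preset, protocol_kind)
        for i in range(count):
            records.append(
                generate_subject(
                    preset,
                    protocol,
                    seed=int(sub_seeds[k]),
                    duration=duration if duration is not None else proto_duration,
                    sampling_rate=sampling_rate,
                    subject_id=f"{group}-{i + 1:02d}",
                )
            )
            k += 1
    return records


def with_overrides(preset: GroupPreset, **kwargs) -> GroupPreset:
    """Convenience wrapper around ``dataclasses.replace`` for presets."""
    return replace(preset, **kwargs)
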