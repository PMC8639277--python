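"""Synthetic cohort generator: determinism, pressure physiology, sigmoid
coupling of burst amplitude, and cohort construction contracts."""

import numpy as np
import pytest

from rsnalab import (
    ConfigurationError,
    InterventionSpec,
    PRESETS,
    SimulationConfig,
    detect_systolic_peaks,
    generate_cohort,
    generate_subject,
)
from rsnalab.synthetic import simulate_pressure, simulate_rsna, with_overrides

WKY = PRESETS["WKY"]


def _quiet(preset, **kw):
    """Preset without stochastic components (structural checks)."""
    base = dict(
        mbp_wander_sd=0.0, noise_sd_uv=0.0, coupling_jitter=0.0,
        tonic_uv=0.0, background_uv=0.0,
    )
    base.update(kw)
    return with_overrides(preset, **base)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        a = generate_subject(WKY, [], seed=123, duration=20.0)
        b = generate_subject(WKY, [], seed=123, duration=20.0)
        assert np.array_equal(a.pressure.values, b.pressure.values)
        assert np.array_equal(a.rsna_raw.values, b.rsna_raw.values)

    def test_different_seed_differs(self):
        a = generate_subject(WKY, [], seed=1, duration=20.0)
        b = generate_subject(WKY, [], seed=2, duration=20.0)
        assert not np.array_equal(a.rsna_raw.values, b.rsna_raw.values)


class TestPressure:
    def test_time_average_tracks_basal_mbp(self):
        # structural: without wander the 60-s time average sits on the basal
        # level; with default wander the across-seed average still does
        quiet = generate_subject(_quiet(WKY), [], seed=0, duration=60.0)
        assert abs(quiet.pressure.values.mean() - WKY.basal_mbp) < 0.1
        devs = [
            generate_subject(WKY, [], seed=s, duration=60.0).pressure.values.mean()
            - WKY.basal_mbp
            for s in range(5)
        ]
        assert abs(np.mean(devs)) < 1.0

    def test_zero_pulse_pressure_equals_mbp_trajectory(self):
        cfg = SimulationConfig(
            preset=with_overrides(WKY, pulse_pressure=0.0), duration=20.0, seed=3
        )
        psim = simulate_pressure(cfg)
        assert np.array_equal(psim.pressure.values, psim.mbp)

    def test_per_beat_excursion_matches_pulse_pressure(self):
        rec = generate_subject(WKY, [], seed=1, duration=60.0)
        idx = np.round(np.array(rec.truth["beat_times"]) * 1000).astype(int)
        pp = [
            rec.pressure.values[a:b].max() - rec.pressure.values[a:b].min()
            for a, b in zip(idx[:-1], idx[1:])
        ]
        assert np.all(np.abs(np.array(pp) - WKY.pulse_pressure) < 0.1 * WKY.pulse_pressure)
        assert rec.pressure.values.min() > 0

    def test_ground_truth_beats_match_detection_within_one_sample(self):
        rec = generate_subject(_quiet(WKY), [], seed=4, duration=60.0)
        beats = detect_systolic_peaks(rec.pressure)
        truth = np.array(rec.truth["beat_times"])
        assert abs(beats.n_beats - truth.size) <= 1
        n = min(beats.n_beats, truth.size)
        assert np.all(np.abs(beats.peak_times[:n] - truth[:n]) <= 1.0 / 1000 + 1e-9)


class TestRsnaCoupling:
    def test_flat_sigmoid_gives_constant_amplitude(self):
        p = _quiet(WKY, sigmoid_upper=50.0 + 1e-6, sigmoid_lower=50.0)
        cfg = SimulationConfig(preset=p, duration=20.0, seed=0, carrier="deterministic")
        psim = simulate_pressure(cfg)
        env = np.abs(simulate_rsna(cfg, psim).values)
        amps = [
            env[int(t * 1000): int(t * 1000) + 150].max()
            for t in psim.beats.peak_times[:-2]
        ]
        assert np.ptp(amps) < 1e-3 * np.mean(amps)

    def test_sigmoid_midpoint_amplitude(self):
        # MBP clamped at p50: burst amplitude is the sigmoid midpoint
        p = _quiet(WKY, basal_mbp=WKY.sigmoid_p50)
        cfg = SimulationConfig(preset=p, duration=30.0, seed=0, carrier="deterministic")
        psim = simulate_pressure(cfg)
        env = np.abs(simulate_rsna(cfg, psim).values)
        amps = [
            env[int(t * 1000): int(t * 1000) + 150].max()
            for t in psim.beats.peak_times[:-2]
        ]
        expected = p.rsna_scale_uv_per_pct * (p.sigmoid_upper + p.sigmoid_lower) / 2.0
        assert abs(np.mean(amps) - expected) < 0.02 * expected

    def test_pressor_ramp_inhibits_rsna(self):
        phe = InterventionSpec("phenylephrine", 60.0, 20.0, "ug/kg/min")
        rec = generate_subject(WKY, [phe], seed=2, duration=160.0)
        rect = np.abs(rec.rsna_raw.values)
        control = rect[:60_000].mean()
        late = rect[130_000:].mean()
        assert late < control

    def test_per_beat_integral_strictly_decreases_with_lagged_mbp(self):
        # deterministic carrier, no noise/jitter: the per-beat rectified
        # integral is an exact image of the sympathoinhibition sigmoid
        p = _quiet(WKY, sigmoid_p50=160.0, sigmoid_k=10.0)
        phe = InterventionSpec(
            "phenylephrine", 60.0, 20.0, "ug/kg/min", kinetics={"ceiling_mmhg": 80.0}
        )
        cfg = SimulationConfig(
            preset=p, protocol=(phe,), duration=160.0, seed=0, carrier="deterministic"
        )
        psim = simulate_pressure(cfg)
        rect = np.abs(simulate_rsna(cfg, psim).values)
        fs = 1000
        pk = psim.beats.peak_times
        lag = int(0.3 * fs)
        mbp_lag = psim.mbp[np.maximum((pk * fs).astype(int) - lag, 0)][:-1]
        cum = np.concatenate(([0.0], np.cumsum(rect))) / fs
        idx = np.round(pk * fs).astype(int)
        integral = cum[idx[1:]] - cum[idx[:-1]]
        band = (mbp_lag > 140.0) & (mbp_lag < 180.0)  # responsive range
        order = np.argsort(mbp_lag[band])
        assert band.sum() > 100
        assert np.all(np.diff(integral[band][order]) < 0)

    def test_alignment_error_on_mismatched_config(self):
        cfg1 = SimulationConfig(preset=WKY, duration=10.0, seed=0)
        cfg2 = SimulationConfig(preset=WKY, duration=12.0, seed=0)
        psim = simulate_pressure(cfg1)
        with pytest.raises(Exception):
            simulate_rsna(cfg2, psim)


class TestProtocolAndCohort:
    def test_subject_carries_events_and_control_window(self):
        dilt = InterventionSpec("diltiazem", 120.0, 1.0, "mg/kg")
        phe = InterventionSpec("phenylephrine", 300.0, 20.0, "ug/kg/min")
        rec = generate_subject(WKY, [dilt, phe], seed=0, duration=420.0)
        assert len(rec.events) == 2
        assert rec.events["time_s"].min() >= 60.0
        assert rec.truth["seed"] == 0

    def test_intervention_before_control_window_rejected(self):
        ev = InterventionSpec("diltiazem", 30.0, 1.0, "mg/kg")
        with pytest.raises(ConfigurationError):
            SimulationConfig(preset=WKY, protocol=(ev,), duration=200.0, seed=0)

    def test_intervention_after_end_rejected(self):
        ev = InterventionSpec("diltiazem", 500.0, 1.0, "mg/kg")
        with pytest.raises(ConfigurationError):
            SimulationConfig(preset=WKY, protocol=(ev,), duration=200.0, seed=0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(preset=WKY, duration=10.0, sampling_rate=200.0, seed=0)

    def test_cohort_counts_and_determinism(self):
        cohort = generate_cohort(
            {"WKY": 9, "SHR": 9, "SHRLN": 10}, seed=5, protocol_kind="basal", duration=30.0
        )
        assert len(cohort) == 28
        assert sum(1 for r in cohort if r.group == "SHRLN") == 10
        again = generate_cohort(
            {"WKY": 9, "SHR": 9, "SHRLN": 10}, seed=5, protocol_kind="basal", duration=30.0
        )
        assert np.array_equal(cohort[3].rsna_raw.values, again[3].rsna_raw.values)
        single = generate_cohort({"WKY": 1}, seed=5, protocol_kind="basal", duration=30.0)
        assert len(single) == 1

    def test_cohort_rejects_zero_count(self):
        with pytest.raises(ConfigurationError):
            generate_cohort({"WKY": 0}, seed=1)
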