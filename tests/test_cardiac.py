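"""Systolic peak detection, per-beat MBP, beat-triggered cumulation and the
RSNA-HR coupling classifier."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rsnalab import (
    BeatSeries,
    ConfigurationError,
    DataError,
    PRESETS,
    Trace,
    detect_systolic_peaks,
    generate_subject,
    mean_bp,
    rsna_hr_correlation,
    triggered_cumulation,
)
from rsnalab.core import DegenerateSeriesError, FlatSignalError
from rsnalab.synthetic import SimulationConfig, simulate_pressure, with_overrides

WKY = PRESETS["WKY"]


def _steady(hr_bpm, seed=0, duration=60.0):
    preset = with_overrides(
        WKY, basal_hr=hr_bpm, mbp_wander_sd=0.0, hr_baroreflex_gain=0.0
    )
    return generate_subject(preset, [], seed=seed, duration=duration)


class TestDetection:
    def test_steady_rate_peak_count(self):
        rec = _steady(360.0)
        beats = detect_systolic_peaks(rec.pressure)
        assert abs(beats.n_beats - 360) <= 1

    def test_constant_trace_is_flat_signal(self):
        with pytest.raises(FlatSignalError):
            detect_systolic_peaks(Trace(np.full(10_000, 120.0), 1000.0))

    def test_too_short_trace_rejected(self):
        with pytest.raises(DataError):
            detect_systolic_peaks(Trace(np.ones(1000), 1000.0))

    def test_two_segment_rates_recovered(self):
        x = np.concatenate(
            [_steady(300.0, seed=1, duration=30.0).pressure.values,
             _steady(420.0, seed=2, duration=30.0).pressure.values]
        )
        beats = detect_systolic_peaks(Trace(x, 1000.0, unit="mmHg"))
        t, hr = beats.peak_times[:-1], beats.hr_inst
        assert abs(hr[(t > 2) & (t < 28)].mean() - 300.0) < 2.0
        assert abs(hr[(t > 32) & (t < 58)].mean() - 420.0) < 2.0


class TestMeanBP:
    def test_offset_plus_zero_mean_waveform(self):
        fs = 1000.0
        t = np.arange(int(5 * fs)) / fs
        x = 120.0 + 10.0 * np.sin(2 * np.pi * 5.0 * t)  # 0.2-s cycles
        beats = BeatSeries(0.05 + 0.2 * np.arange(24))  # at the sine peaks
        out = mean_bp(Trace(x, fs, unit="mmHg"), beats)
        assert np.allclose(out.values, 120.0, atol=1e-9)

    def test_square_wave_mean(self):
        fs = 1000.0
        cycle = np.concatenate([np.full(100, 160.0), np.full(100, 80.0)])
        x = np.tile(cycle, 25)
        beats = BeatSeries(0.2 * np.arange(25))
        out = mean_bp(Trace(x, fs), beats)
        assert np.allclose(out.values, 120.0)

    def test_matches_generator_mbp_trajectory(self):
        cfg = SimulationConfig(preset=WKY, duration=60.0, seed=9)
        psim = simulate_pressure(cfg)
        out = mean_bp(psim.pressure, psim.beats)
        idx = np.round(out.times * 1000).astype(int)
        assert np.all(np.abs(out.values - psim.mbp[idx]) < 2.0)

    def test_ibi_weighted_mean_conserves_time_average(self):
        cfg = SimulationConfig(preset=WKY, duration=30.0, seed=4)
        psim = simulate_pressure(cfg)
        beats = psim.beats
        out = mean_bp(psim.pressure, beats)
        i0 = int(round(beats.peak_times[0] * 1000))
        i1 = int(round(beats.peak_times[-1] * 1000))
        # weights = actual sample counts per beat interval
        counts = np.diff(np.round(beats.peak_times * 1000).astype(int))
        total = (out.values * counts).sum()
        assert np.isclose(total, psim.pressure.values[i0:i1].sum(), rtol=1e-12)


class TestTriggeredCumulation:
    def test_constant_signal(self):
        beats = BeatSeries(0.2 * np.arange(40))
        out = triggered_cumulation(Trace(np.ones(10_000), 1000.0), beats, 0.5)
        assert np.allclose(out.values, 0.5)

    def test_zero_window_rejected(self):
        beats = BeatSeries(0.2 * np.arange(40))
        with pytest.raises(ConfigurationError):
            triggered_cumulation(Trace(np.ones(10_000), 1000.0), beats, 0.0)

    def test_trailing_windows_dropped(self):
        beats = BeatSeries(0.2 * np.arange(50))  # last peak at 9.8 s
        out = triggered_cumulation(Trace(np.ones(10_000), 1000.0), beats, 0.5)
        # peaks after 9.5 s have no room for a full 0.5-s window
        assert out.values.size == 48

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        x = np.abs(rng.normal(size=20_000))
        peaks = np.cumsum(rng.uniform(0.1, 0.5, size=40))
        beats = BeatSeries(peaks)
        out = triggered_cumulation(Trace(x, 1000.0), beats, 0.5)
        oracle = []
        for t in out.times:
            i = int(round(t * 1000))
            oracle.append(x[i:i + 500].sum() / 1000.0)
        assert np.allclose(out.values, oracle, atol=1e-12)


class TestCoupling:
    def test_proportional_series_is_perfectly_coupled(self):
        rng = np.random.default_rng(0)
        hr = 400 + rng.normal(size=300)
        res = rsna_hr_correlation(3.0 * hr, hr)
        assert res.r == pytest.approx(1.0)
        assert res.best_lag == 0
        assert res.classification == "intact"

    def test_independent_white_noise_is_altered(self):
        rng = np.random.default_rng(42)
        res = rsna_hr_correlation(rng.normal(size=500), rng.normal(size=500))
        assert abs(res.r) < 0.3
        assert res.classification == "altered"

    def test_lagged_copy_recovers_lag(self):
        # hr[i] = rsna[i - 3]: exact correlation at lag -3 (RSNA lags HR
        # pairing convention: lag L pairs rsna[i] with hr[i + L])
        rng = np.random.default_rng(1)
        x = np.random.default_rng(1).normal(size=400)
        res = rsna_hr_correlation(x[:-3], x[3:], max_lag_beats=5)
        assert res.best_lag == -3
        assert res.r == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None)
    @given(
        a=st.floats(min_value=0.1, max_value=50.0),
        b=st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_affine_invariance(self, a, b):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=200), rng.normal(size=200)
        r0 = rsna_hr_correlation(x, y).r
        r1 = rsna_hr_correlation(a * x + b, y).r
        assert r1 == pytest.approx(r0, abs=1e-9)

    def test_too_few_beats_rejected(self):
        with pytest.raises(DataError):
            rsna_hr_correlation(np.ones(50) + np.arange(50), np.arange(50.0))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSeriesError):
            rsna_hr_correlation(np.ones(200), np.arange(200.0))
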