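"""Baroreflex curve binning/averaging, slope and plateau estimation, and
drug-response quantification."""

import numpy as np
import pytest

from rsnalab import (
    BaroreflexCurve,
    InterventionSpec,
    PRESETS,
    RSNAModel,
    average_curves,
    bezold_jarisch_response,
    build_baroreflex_curve,
    descending_slope,
    drug_response,
    generate_subject,
    plateau_pressure,
)
from rsnalab.core import DataError, InsufficientRangeError, NoPlateauError


def _curve(centers, values, n=10.0):
    centers = np.asarray(centers, dtype=float)
    values = np.asarray(values, dtype=float)
    return BaroreflexCurve(
        centers - 2.5, values, np.zeros_like(values), np.full(values.size, float(n))
    )


def _sigmoid(p, upper, lower, p50, k):
    return lower + (upper - lower) / (1.0 + np.exp((p - p50) / k))


class TestBinning:
    def test_known_pairs(self):
        c = build_baroreflex_curve(
            [52.0, 53.0, 57.0, 58.0], [100.0, 90.0, 80.0, 70.0], min_bins=2
        )
        assert np.array_equal(c.bin_left, [50.0, 55.0])
        assert np.allclose(c.mean_pct, [95.0, 75.0])
        assert np.array_equal(c.n, [2.0, 2.0])

    def test_edge_value_goes_to_upper_bin(self):
        c = build_baroreflex_curve([55.0], [42.0], min_bins=1)
        assert c.bin_left[0] == 55.0

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        mbp = rng.uniform(60.0, 180.0, size=500)
        rsna = rng.uniform(0.0, 300.0, size=500)
        c = build_baroreflex_curve(mbp, rsna)
        groups: dict[float, list[float]] = {}
        for m, r in zip(mbp, rsna):
            groups.setdefault(np.floor(m / 5.0) * 5.0, []).append(r)
        for left, mean, n in zip(c.bin_left, c.mean_pct, c.n):
            assert n == len(groups[left])
            assert mean == pytest.approx(np.mean(groups[left]), rel=1e-12)
        assert int(c.n.sum()) == 500  # every pair lands in exactly one bin

    def test_too_few_bins_rejected(self):
        with pytest.raises(InsufficientRangeError):
            build_baroreflex_curve([100.0, 101.0], [50.0, 60.0])


class TestAveraging:
    def test_identical_curves_average_to_themselves(self):
        c = _curve([102.5, 107.5, 112.5], [100.0, 60.0, 20.0])
        g = average_curves([c, c])
        assert np.allclose(g.mean_pct, c.mean_pct)
        assert np.allclose(g.sem, 0.0)

    def test_opposite_curves(self):
        a = _curve([102.5], [100.0])
        b = _curve([102.5], [0.0])
        g = average_curves([a, b])
        assert g.mean_pct[0] == pytest.approx(50.0)
        assert g.sem[0] == pytest.approx(50.0)

    def test_bins_in_single_subject_dropped(self):
        a = _curve([102.5, 107.5], [100.0, 50.0])
        b = _curve([102.5], [80.0])
        g = average_curves([a, b])
        assert np.array_equal(g.bin_left, [100.0])

    def test_single_curve_rejected(self):
        with pytest.raises(DataError):
            average_curves([_curve([102.5], [1.0])])


class TestSlope:
    def test_exact_line(self):
        centers = np.arange(102.5, 150.0, 5.0)
        values = 100.0 - 2.0 * (centers - 100.0)
        est = descending_slope(_curve(centers, values))
        assert est.slope == pytest.approx(-2.0)
        assert est.r_squared == pytest.approx(1.0)

    def test_flat_curve_rejected(self):
        with pytest.raises(InsufficientRangeError):
            descending_slope(_curve([102.5, 107.5, 112.5, 117.5], [50.0] * 4))

    def test_sigmoid_slope_matches_numeric_derivative_oracle(self):
        centers = np.arange(62.5, 180.0, 5.0)
        values = _sigmoid(centers, 100.0, 0.0, 120.0, 5.0)
        est = descending_slope(_curve(centers, values))
        # oracle: mean numeric derivative of the sigmoid over the fitted band
        lo, hi = est.fit_range
        p = np.linspace(lo, hi, 2001)
        d = np.gradient(_sigmoid(p, 100.0, 0.0, 120.0, 5.0), p)
        assert abs(est.slope - d.mean()) / abs(d.mean()) < 0.15


class TestPlateau:
    def test_piecewise_flat_tail(self):
        centers = np.arange(102.5, 160.0, 5.0)
        values = np.where(centers < 135.0, 100.0 - 2.5 * (centers - 100.0), 0.0)
        values[centers >= 135.0] = 0.0
        assert plateau_pressure(_curve(centers, values)) == pytest.approx(137.5)

    def test_monotone_curve_has_no_plateau(self):
        centers = np.arange(102.5, 150.0, 5.0)
        values = 100.0 - 2.0 * (centers - 100.0)
        with pytest.raises(NoPlateauError):
            plateau_pressure(_curve(centers, values))

    def test_sigmoid_plateau_matches_closed_form_inversion(self):
        p50, k = 135.0, 4.0
        centers = np.arange(62.5, 230.0, 5.0)
        values = _sigmoid(centers, 100.0, 0.0, p50, k)
        est = plateau_pressure(_curve(centers, values), tol_pct=5.0)
        analytic = p50 + k * np.log((1 - 0.05) / 0.05)
        assert abs(est - analytic) <= 10.0


def _step_series(baseline, extremum, event_time=120.0, duration=200.0):
    times = np.arange(0.0, duration, 0.15)
    vals = np.where(times < event_time, float(baseline), float(extremum))
    return times, vals


class TestDrugResponse:
    def test_signed_delta_from_step_inputs(self):
        # baseline 126 mmHg, post-vasodilator nadir 49 -> delta -77
        times, mbp = _step_series(126.0, 49.0)
        _, hr = _step_series(437.0, 449.0)
        ev = InterventionSpec("diltiazem", 120.0, 1.0, "mg/kg")
        resp = drug_response(times, mbp, hr, ev)
        assert resp.delta_mbp == pytest.approx(-77.0)
        assert resp.baseline_mbp == pytest.approx(126.0)

    def test_pressor_bradycardia_delta(self):
        # baseline HR 355 bpm, during-infusion 329 -> delta -26
        times, mbp = _step_series(156.0, 237.0)
        _, hr = _step_series(355.0, 329.0)
        ev = InterventionSpec("phenylephrine", 120.0, 20.0, "ug/kg/min")
        resp = drug_response(times, mbp, hr, ev)
        assert resp.delta_hr == pytest.approx(-26.0)
        assert resp.delta_mbp == pytest.approx(+81.0)

    def test_event_outside_series_rejected(self):
        times, mbp = _step_series(126.0, 49.0)
        ev = InterventionSpec("diltiazem", 500.0, 1.0, "mg/kg")
        with pytest.raises(DataError):
            drug_response(times, mbp, mbp, ev)


class TestBezoldJarisch:
    def test_known_inhibition(self):
        times = np.arange(0.0, 200.0, 0.15)
        rsna = np.where((times >= 120.0) & (times < 150.0), 20.0, 100.0)
        mbp = np.where((times >= 120.0) & (times < 150.0), 100.0, 120.0)
        hr = np.full_like(times, 400.0)
        ev = InterventionSpec("cpbg", 120.0, 3.0, "ug/kg")
        resp = bezold_jarisch_response(times, rsna, mbp, hr, ev)
        assert resp.rsna_inhibition_pct == pytest.approx(-80.0, abs=1.0)
        assert not resp.flags

    def test_non_responder_flagged(self):
        times = np.arange(0.0, 200.0, 0.15)
        rsna = np.where(times >= 120.0, 130.0, 100.0)
        ev = InterventionSpec("cpbg", 120.0, 3.0, "ug/kg")
        resp = bezold_jarisch_response(times, rsna, rsna, rsna + 300.0, ev)
        assert resp.rsna_inhibition_pct >= 0.0
        assert "non_responder" in resp.flags

    def test_simulated_kernel_recovery(self):
        # inhibition-only kernel (depth 0.70): the pipeline recovers the
        # programmed sympathoinhibition within +-5 percentage points
        ev = InterventionSpec(
            "cpbg", 120.0, 3.0, "ug/kg",
            kinetics={"inhibition_depth": 0.70, "mbp_drop_mmhg": 0.0, "hr_drop_bpm": 0.0},
        )
        rec = generate_subject(PRESETS["WKY"], [ev], seed=5, duration=240.0)
        results = RSNAModel(rec).fit()
        (resp,) = [r for r in results.responses if r.agent == "cpbg"]
        assert resp.rsna_inhibition_pct == pytest.approx(-70.0, abs=5.0)
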