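"""Movement scoring oracles: template fit, cost, peaks, triphasic rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spinarm import evaluate as ev
from spinarm.evaluate import Peak, PeakSet

from conftest import make_trace, template_trace


class TestMinJerkTemplate:
    def test_endpoints(self):
        assert ev.minjerk_template(40.0, 0.8, 5.0, 5.0) == 0.0
        assert ev.minjerk_template(40.0, 0.8, 5.0, 5.8) == pytest.approx(40.0)

    def test_flat_outside_movement(self):
        t = np.array([0.0, 4.9, 7.0, 10.0])
        out = ev.minjerk_template(40.0, 0.8, 5.0, t)
        assert out[0] == out[1] == 0.0
        assert out[2] == out[3] == pytest.approx(40.0)

    @pytest.mark.parametrize("a, d", [(10.0, 0.3), (40.0, 0.8), (110.0, 2.0)])
    def test_peak_speed_identity(self, a, d):
        """Numerical max of the template derivative equals 1.875 A / D."""
        t = np.linspace(5.0, 5.0 + d, 20001)
        x = ev.minjerk_template(a, d, 5.0, t)
        v_max = np.max(np.gradient(x, t))
        assert v_max == pytest.approx(ev.minjerk_peak_speed(a, d), rel=1e-4)

    def test_duration_5_95_fraction(self):
        # fraction solved from the quintic profile itself
        lo = ev._phase(0.05)
        hi = ev._phase(0.95)
        assert ev.duration_5_95(1.0) == pytest.approx(hi - lo)
        assert 0.55 < ev.duration_5_95(1.0) < 0.65


class TestFitMinJerk:
    @pytest.mark.parametrize("a, d", [(10.0, 0.3), (25.0, 0.5), (42.88, 0.8),
                                      (70.0, 1.2), (110.0, 2.0)])
    def test_recovers_noiseless_parameters(self, a, d):
        fit = ev.fit_minjerk(template_trace(a, d))
        assert fit.amplitude == pytest.approx(a, rel=0.01)
        assert fit.duration == pytest.approx(d, rel=0.02)
        assert fit.mse < 1e-6

    def test_noise_floor_matches_noise_variance(self):
        """White noise of s.d. 0.5 deg leaves mse ~ 0.25 deg^2."""
        sd = 0.5
        fit = ev.fit_minjerk(template_trace(40.0, 0.8, noise_sd=sd, seed=4))
        assert fit.mse == pytest.approx(sd**2, rel=0.15)

    def test_flat_trace_is_flagged(self):
        m = ev.evaluate_movement(make_trace(np.zeros(1001)))
        assert not m.valid
        assert m.amplitude == pytest.approx(0.0)

    def test_extension_trace_is_wrong_direction(self):
        trace = template_trace(-30.0, 0.8, start=60.0)
        fit = ev.fit_minjerk(trace)
        assert fit.wrong_direction


class TestCocontractionPenalty:
    def test_both_at_threshold_gives_zero(self):
        t = np.arange(1001) * 0.01
        v = np.full_like(t, -60.0)
        assert ev.cocontraction_penalty(v, v, t, (2, 5)) == 0.0

    def test_both_at_minus_50_matches_hand_computation(self):
        """(V-Vthr)*(V-Vthr) = 10*10 mV^2, x100 -> 10,000."""
        t = np.arange(1001) * 0.01
        v = np.full_like(t, -50.0)
        assert ev.cocontraction_penalty(v, v, t, (2, 5)) == pytest.approx(10000.0)

    def test_one_sided_activity_is_free(self):
        t = np.arange(1001) * 0.01
        above = np.full_like(t, -40.0)
        below = np.full_like(t, -65.0)
        assert ev.cocontraction_penalty(above, below, t, (2, 5)) == 0.0
        assert ev.cocontraction_penalty(below, above, t, (7, 10)) == 0.0

    def test_adding_cocontraction_never_decreases_cost(self):
        trace = template_trace(40.0, 0.8)
        base = ev.cost(trace, ev.fit_minjerk(trace))
        noisy = template_trace(40.0, 0.8)
        noisy.potentials["FlxAlpha"] = np.full(1001, -55.0)
        noisy.potentials["ExtAlpha"] = np.full(1001, -58.0)
        withco = ev.cost(noisy, ev.fit_minjerk(noisy))
        assert withco.total_cost >= base.total_cost
        assert withco.penalty_prep > 0 and withco.penalty_main > 0


class TestCost:
    def test_perfect_template_movement_costs_nothing(self):
        trace = template_trace(40.0, 0.8)
        c = ev.cost(trace, ev.fit_minjerk(trace))
        assert c.total_cost < 1e-6

    def test_preparatory_drift_alone_invalidates(self):
        """A 5 deg drift during the hold phase pushes tracking above 1."""
        t = np.arange(1001) * 0.01
        angle = np.clip((t - 2.0) * (5.0 / 3.0), 0.0, 5.0)
        m = ev.evaluate_movement(make_trace(angle))
        assert m.cost > 1.0
        assert not m.valid

    def test_valid_movement_class_is_below_one(self):
        m = ev.evaluate_movement(template_trace(42.88, 0.8))
        assert m.cost < 1.0
        assert m.valid


def _brute_force_peaks(x, t, baseline=-60.0, tol=1e-9):
    """Independent reference peak scan (naive per-sample neighbor walk)."""
    n = len(x)
    peaks = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if x[i] > baseline + tol:
            left_lower = False
            k = i - 1
            if k >= 0:
                left_lower = x[k] < x[i]
            right_lower = False
            k = j + 1
            if k < n:
                right_lower = x[k] < x[i]
            if left_lower and right_lower:
                peaks.append((i + j) // 2)
        i = j + 1
    return [t[p] for p in peaks]


class TestDetectPeaks:
    def test_flat_baseline_has_no_peaks(self):
        x = np.full(500, -60.0)
        assert len(ev.detect_peaks(x)) == 0

    def test_single_bump_single_peak(self):
        t = np.arange(1001) * 0.01
        x = -60.0 + 30.0 * np.exp(-((t - 5.3) ** 2) / 0.01)
        ps = ev.detect_peaks(x, t)
        assert len(ps) == 1
        assert ps.peaks[0].time == pytest.approx(5.3, abs=0.01)
        assert ps.peaks[0].potential == pytest.approx(-30.0, abs=0.1)

    def test_plateau_reports_single_center_peak(self):
        x = np.full(100, -60.0)
        x[40:61] = -40.0
        ps = ev.detect_peaks(x)
        assert len(ps) == 1
        assert ps.peaks[0].time == 50.0

    def test_equivalence_with_brute_force_on_random_signals(self):
        """1,000 random piecewise-linear signals, exact agreement."""
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            n_knots = rng.integers(4, 12)
            knot_t = np.sort(rng.choice(np.arange(1, 199), n_knots, replace=False))
            knot_v = rng.uniform(-70, -20, n_knots)
            t = np.arange(200, dtype=float)
            x = np.interp(t, np.concatenate([[0], knot_t, [199]]),
                          np.concatenate([[-60], knot_v, [-60]]))
            if rng.random() < 0.3:  # sprinkle exact plateaus
                i = rng.integers(20, 150)
                x[i:i + rng.integers(2, 8)] = x[i]
            got = ev.detect_peaks(x, t).times
            want = _brute_force_peaks(x, t)
            assert got == want

    def test_minima_bracket_every_peak(self):
        rng = np.random.default_rng(9)
        x = -60 + np.abs(np.cumsum(rng.normal(0, 1.5, 300)))
        x[0] = x[-1] = -60.0
        ps = ev.detect_peaks(x)
        for p in ps.peaks:
            assert p.left_min_time <= p.time <= p.right_min_time


class TestClassifyTriphasic:
    def _ps(self, times, baseline=-60.0):
        peaks = [Peak(t, -30.0, t - 0.05, t + 0.05) for t in times]
        return PeakSet(peaks=peaks, baseline=baseline)

    def test_textbook_triphasic(self):
        lab = ev.classify_triphasic(self._ps([5.1, 5.6]), self._ps([5.35]))
        assert lab.is_triphasic
        assert lab.ant.time == 5.35

    def test_single_burst_pair_is_biphasic(self):
        lab = ev.classify_triphasic(self._ps([5.1]), self._ps([5.4]))
        assert not lab.is_triphasic

    def test_antagonist_before_both_agonist_bursts_fails(self):
        lab = ev.classify_triphasic(self._ps([5.2, 5.7]), self._ps([5.0]))
        assert not lab.is_triphasic

    @given(shift=st.floats(-2.0, 2.0))
    @settings(max_examples=30, deadline=None)
    def test_invariant_under_uniform_time_shift(self, shift):
        flx = self._ps([5.1 + shift, 5.6 + shift])
        ext = self._ps([5.35 + shift])
        assert ev.classify_triphasic(flx, ext).is_triphasic


class TestEvaluateMovement:
    def test_small_amplitude_rejected(self):
        m = ev.evaluate_movement(template_trace(8.0, 0.5))
        assert not m.valid
        assert "amplitude-range" in m.rejection_reasons

    def test_slow_movement_rejected(self):
        m = ev.evaluate_movement(template_trace(40.0, 3.4))
        assert not m.valid
        assert "too-slow" in m.rejection_reasons
        assert m.duration > 2.0

    def test_failed_trial_is_unstable(self):
        trace = template_trace(40.0, 0.8)
        trace.failed = True
        m = ev.evaluate_movement(trace)
        assert not m.valid
        assert m.rejection_reasons == {"unstable"}

    def test_representative_valid_movement(self):
        m = ev.evaluate_movement(template_trace(42.88, 0.8))
        assert m.valid
        assert m.amplitude == pytest.approx(42.88, rel=0.01)
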