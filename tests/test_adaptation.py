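"""Pre/post-midpoint statistics, Wilcoxon tests, and trajectory analytics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pulsenav.adaptation import (
    DeviationSeries,
    Trajectory,
    angular_deviation,
    detect_reversals,
    pre_post_midpoint_means,
    pulse_derivative_correlation,
    pulse_phase_of_reversals,
    smooth_track,
    wilcoxon_test,
)
from pulsenav.errors import DataError, ParameterError, UndefinedTestError
from pulsenav.pulses import CalciumTrace
from pulsenav.stimulus import generate_profile

T = np.arange(0.0, 1200.0, 1.0 / 1.4)
TANH = generate_profile(
    "tanh", {"baseline": 1.0, "amplitude": 100.0, "t_mid": 600.0, "steepness": 0.01}, T
)


def trace_from(values):
    return CalciumTrace("w0", "AWA", T, np.asarray(values, dtype=float))


class TestPrePostMidpoint:
    def test_symmetric_activity_gives_equal_means(self):
        sym = np.exp(-((T - 600.0) ** 2) / (2 * 50.0**2))
        before, after = pre_post_midpoint_means(trace_from(sym), TANH)
        assert before == pytest.approx(after, rel=1e-6)

    def test_activity_only_before_midpoint(self):
        v = np.where(T < 600.0, 1.0, 0.0)
        before, after = pre_post_midpoint_means(trace_from(v), TANH)
        assert before > 0 and after == 0.0

    def test_window_extending_past_trace_raises(self):
        short = CalciumTrace("w", "AWA", T[: T.size // 2 + 20], np.ones(T.size // 2 + 20))
        with pytest.raises(DataError):
            pre_post_midpoint_means(short, TANH, window=300.0)

    def test_mild_truncation_warns_but_returns(self):
        # after-window covered ~79%: warn, do not fail
        n = int(np.searchsorted(T, 600.0 + 0.79 * 150.0))
        shortish = CalciumTrace("w", "AWA", T[:n], np.ones(n))
        with pytest.warns(UserWarning, match="truncated"):
            before, after = pre_post_midpoint_means(shortish, TANH, window=150.0)
        assert before == after == 1.0


def signed_rank_enumeration(diffs, side="greater"):
    """Exhaustive 2^n sign-flip null for the Wilcoxon signed-rank test."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    count = 0
    total = 0
    for signs in itertools.product((0, 1), repeat=len(d)):
        w = ranks[np.array(signs, dtype=bool)].sum()
        total += 1
        if side == "greater" and w >= w_obs:
            count += 1
        elif side == "less" and w <= w_obs:
            count += 1
    return count / total


class TestWilcoxon:
    def test_five_positive_differences_one_sided(self):
        stat, p = wilcoxon_test([1.0, 2.0, 0.5, 3.0, 1.5], mode="signed_rank_paired",
                                side="greater")
        assert p == pytest.approx(1.0 / 32.0)

    @pytest.mark.parametrize("n", [4, 6, 8, 10])
    def test_exact_mode_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = rng.standard_normal(n) + 0.3
            _, p = wilcoxon_test(d, mode="signed_rank_paired", side="greater")
            assert p == pytest.approx(signed_rank_enumeration(d, "greater"))

    def test_antisymmetric_swap_flips_one_sided_p(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(12)
        b = rng.standard_normal(12)
        _, p_ab = wilcoxon_test(a, b, side="greater")
        _, p_ba = wilcoxon_test(b, a, side="less")
        assert p_ab == pytest.approx(p_ba)

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_test(np.zeros(8), mode="signed_rank_paired")

    def test_rank_sum_matches_scipy_exact(self):
        rng = np.random.default_rng(4)
        a, b = rng.standard_normal(8), rng.standard_normal(9) + 0.5
        stat, p = wilcoxon_test(a, b, mode="rank_sum_independent", side="two-sided")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert p == pytest.approx(ref.pvalue)

    def test_null_calibration_uniform_p(self):
        # exact-test p-values are discrete, hence mildly conservative; with
        # n = 25 pairs the atoms are fine enough for a KS uniformity check
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(500):
            d = rng.standard_normal(25)
            _, p = wilcoxon_test(d, mode="signed_rank_paired", side="greater")
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestPulseDerivativeCorrelation:
    def pulse_table(self, times, amps, worm="w0"):
        return pd.DataFrame(
            {"worm_id": worm, "peak_time_s": times, "amplitude": amps}
        )

    def test_amplitude_proportional_to_derivative_gives_r_one(self):
        prof = generate_profile(
            "exp_derivative", {"baseline": 0.0, "c0": 1.0, "tau_growth": 300.0}, T
        )
        times = np.linspace(100, 1100, 12)
        d1 = np.interp(times, prof.times, prof.d1)
        tab = self.pulse_table(times, 3.0 * d1)
        r, p = pulse_derivative_correlation(tab, prof, "amplitude")
        assert r == pytest.approx(1.0, abs=1e-9)
        assert p < 1e-6

    def test_independent_quantity_gives_small_r(self):
        prof = generate_profile(
            "exp_derivative", {"baseline": 0.0, "c0": 1.0, "tau_growth": 300.0}, T
        )
        big_p = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            times = np.sort(rng.uniform(50, 1150, 20))
            tab = self.pulse_table(times, rng.uniform(0.5, 1.5, 20))
            r, p = pulse_derivative_correlation(tab, prof, "amplitude")
            if p > 0.05:
                big_p += 1
        assert big_p >= 34  # ~95% expected under the null

    def test_intervals_inverse_to_derivative_give_negative_r(self):
        prof = generate_profile(
            "exp_derivative", {"baseline": 0.0, "c0": 1.0, "tau_growth": 300.0}, T
        )
        times = np.linspace(100, 1100, 15)
        d1 = np.interp(times, prof.times, prof.d1)
        tab = pd.DataFrame(
            {
                "worm_id": "w0",
                "peak_time_s": times,
                "amplitude": np.ones_like(times),
                "interval_s": 1.0 / d1,
            }
        )
        r, _ = pulse_derivative_correlation(tab, prof, "interval")
        assert r < 0

    def test_too_few_pulses_rejected(self):
        tab = self.pulse_table([100.0, 200.0], [1.0, 2.0])
        with pytest.raises(DataError):
            pulse_derivative_correlation(tab, TANH, "amplitude")


class TestSmoothTrack:
    def make_noisy_line(self, seed=0, n=200, sd=0.05):
        rng = np.random.default_rng(seed)
        t = np.arange(n) * 0.5
        x = 0.1 * t + sd * rng.standard_normal(n)
        y = 0.05 * t + sd * rng.standard_normal(n)
        return Trajectory(t, x, y, target=(100.0, 100.0)), t

    def test_huge_penalty_collapses_to_straight_line(self):
        traj, t = self.make_noisy_line()
        sm = smooth_track(traj, roughness=1e12)
        # residuals from the best straight line are negligible
        coef = np.polyfit(t, sm.x, 1)
        span = sm.x.max() - sm.x.min()
        assert np.max(np.abs(sm.x - np.polyval(coef, t))) <= 1e-6 * span

    def test_zero_penalty_interpolates(self):
        traj, _ = self.make_noisy_line()
        sm = smooth_track(traj, roughness=0.0)
        assert np.allclose(sm.x, traj.x) and np.allclose(sm.y, traj.y)

    def test_auto_smoothing_denoises_straight_walk(self):
        sd = 0.05
        traj, t = self.make_noisy_line(seed=3, sd=sd)
        sm = smooth_track(traj, roughness="auto")
        rmse = np.sqrt(np.mean((sm.x - 0.1 * t) ** 2 + (sm.y - 0.05 * t) ** 2))
        noisy_rmse = np.sqrt(np.mean((traj.x - 0.1 * t) ** 2 + (traj.y - 0.05 * t) ** 2))
        assert rmse < noisy_rmse < 2 * sd

    def test_duplicate_timestamps_rejected(self):
        t = np.array([0.0, 1.0, 1.0, 2.0])
        with pytest.raises(DataError):
            Trajectory(t, t, t, (0.0, 0.0))


class TestAngularDeviation:
    def test_straight_toward_target_is_zero(self):
        t = np.arange(10.0)
        traj = Trajectory(t, t, np.zeros_like(t), target=(100.0, 0.0))
        dev = angular_deviation(traj)
        assert np.allclose(dev.deviation, 0.0, atol=1e-9)

    def test_straight_away_is_180(self):
        t = np.arange(10.0)
        traj = Trajectory(t, -t, np.zeros_like(t), target=(100.0, 0.0))
        dev = angular_deviation(traj)
        assert np.allclose(dev.deviation, 180.0, atol=1e-9)

    def test_circular_orbit_is_90(self):
        t = np.linspace(0, 2 * np.pi, 400)
        traj = Trajectory(t, np.cos(t), np.sin(t), target=(0.0, 0.0))
        dev = angular_deviation(traj)
        assert np.allclose(dev.deviation[1:-1], 90.0, atol=0.5)

    def test_invariant_under_rotation_and_translation(self):
        rng = np.random.default_rng(5)
        t = np.arange(50.0)
        x = np.cumsum(rng.standard_normal(50))
        y = np.cumsum(rng.standard_normal(50))
        target = (5.0, -3.0)
        dev0 = angular_deviation(Trajectory(t, x, y, target))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        xy = R @ np.vstack([x, y]) + np.array([[10.0], [-20.0]])
        tgt = R @ np.array(target) + np.array([10.0, -20.0])
        dev1 = angular_deviation(Trajectory(t, xy[0], xy[1], tuple(tgt)))
        assert np.allclose(dev0.deviation, dev1.deviation, atol=1e-8, equal_nan=True)


class TestDetectReversals:
    def about_face_track(self, turn_times, n=200, dt=0.5, excursion=2.0):
        # target-directed run with brief 180-degree excursions at turn_times;
        # each excursion onset produces an abrupt deviation increase
        t = np.arange(n) * dt
        away = np.zeros(n, dtype=bool)
        for tt in turn_times:
            away |= (t >= tt) & (t < tt + excursion)
        heading = np.where(away, np.pi, 0.0)
        x = np.concatenate([[0.0], np.cumsum(np.cos(heading[:-1]) * dt)])
        y = np.concatenate([[0.0], np.cumsum(np.sin(heading[:-1]) * dt)])
        return Trajectory(t, x, y, target=(1000.0, 0.0))

    def test_single_about_face_detected_once(self):
        traj = self.about_face_track([50.0])
        dev = angular_deviation(traj)
        events = detect_reversals(dev, jump=90.0, horizon=1.0)
        assert len(events) == 1
        assert abs(events[0] - 50.0) <= 1.5

    def test_monotone_approach_no_events(self):
        t = np.arange(100.0)
        traj = Trajectory(t, t, np.zeros_like(t), target=(1000.0, 0.0))
        events = detect_reversals(angular_deviation(traj))
        assert len(events) == 0

    def test_two_separated_about_faces(self):
        traj = self.about_face_track([30.0, 60.0])
        dev = angular_deviation(traj)
        events = detect_reversals(dev, jump=90.0, horizon=1.0)
        assert len(events) == 2


class TestPulsePhase:
    def test_no_reversals_gives_defined_empty_event_output(self):
        trace = trace_from(np.exp(-((T - 600.0) ** 2) / 5000.0))
        dev = DeviationSeries(T, np.full_like(T, 10.0))
        out = pulse_phase_of_reversals(trace, dev, np.array([]), np.array([840]))
        assert set(out[out.kind == "half"]["half"]) == {"first", "second"}
        assert (out.kind == "event").sum() == 0

    def test_event_at_peak_assigned_to_second_half(self):
        trace = trace_from(np.exp(-((T - 600.0) ** 2) / 5000.0))
        peak = int(np.argmax(trace.values))
        dev = DeviationSeries(T, np.full_like(T, 10.0))
        out = pulse_phase_of_reversals(
            trace, dev, np.array([trace.times[peak]]), np.array([peak])
        )
        ev = out[out.kind == "event"].iloc[0]
        assert ev["half"] == "second"
        assert ev["activity_fraction"] == pytest.approx(1.0, rel=1e-6)

    def test_event_outside_pulses_labelled_between(self):
        out = pulse_phase_of_reversals(
            trace_from(np.ones_like(T)),
            DeviationSeries(T, np.zeros_like(T)),
            np.array([5.0]),
            np.array([], dtype=int),
        )
        assert out.iloc[0]["half"] == "between-pulse"
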