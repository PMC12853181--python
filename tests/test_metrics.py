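"""Discrimination indices, analysis windows, time courses, cohort stats."""

import numpy as np
import pandas as pd
import pytest

from kagenor import metrics, stats
from kagenor.core import ExplorationSeries, PhaseSchedule
from kagenor.synthetic import simulate_cohort

from conftest import short_config


def make_series(n, true_frames_left=(), true_frames_right=(), frame_rate=2.0):
    left = np.zeros(n, bool)
    right = np.zeros(n, bool)
    left[list(true_frames_left)] = True
    right[list(true_frames_right)] = True
    return ExplorationSeries(left, right, frame_rate=frame_rate)


def short_schedule(novel_side="left"):
    return PhaseSchedule.standard(
        habituation_s=600.0, sample_s=1800.0, retention_s=1800.0, test_s=1800.0,
        novel_side=novel_side,
    )


class TestBinning:
    def test_saturated_bin(self):
        series = make_series(120, true_frames_left=range(120))
        binned = metrics.bin_series(series)
        assert binned.seconds["left"][0] == pytest.approx(60.0)

    def test_all_false_gives_zero_bins(self):
        binned = metrics.bin_series(make_series(600))
        assert np.all(binned.total == 0)

    def test_conservation(self):
        rng = np.random.default_rng(3)
        left = rng.random(1000) < 0.1
        right = (rng.random(1000) < 0.1) & ~left
        series = ExplorationSeries(left, right)
        binned = metrics.bin_series(series)
        assert binned.total.sum() == pytest.approx((left.sum() + right.sum()) * 0.5)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            metrics.bin_series(make_series(100), bin_width_s=0.75)


class TestSmoothing:
    def test_impulse_preserves_mass_in_interior(self):
        x = np.zeros(101)
        x[50] = 1.0
        y = metrics.smooth_for_display(x, sigma_bins=4.0)
        assert y.sum() == pytest.approx(1.0, abs=1e-9)
        assert y[50] == y.max()

    def test_constant_preserved(self):
        y = metrics.smooth_for_display(np.full(50, 3.3), sigma_bins=4.0)
        assert np.allclose(y, 3.3)

    def test_sigma_zero_is_identity(self):
        x = np.arange(10.0)
        assert np.array_equal(metrics.smooth_for_display(x, 0.0), x)


class TestDiscriminationIndex:
    def test_novelty_factor_gives_quarter(self):
        assert metrics.discrimination_index(167.0, 100.0) == pytest.approx(0.2509, abs=5e-4)

    @pytest.mark.parametrize("t", [1.0, 5.0, 123.4])
    def test_equal_times_give_zero(self, t):
        assert metrics.discrimination_index(t, t) == 0.0

    def test_boundary_is_one(self):
        assert metrics.discrimination_index(42.0, 0.0) == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        for a, b in rng.random((50, 2)) * 100:
            di = metrics.discrimination_index(a, b)
            assert di == pytest.approx(-metrics.discrimination_index(b, a))
            assert -1.0 <= di <= 1.0

    def test_zero_zero_undefined(self):
        assert np.isnan(metrics.discrimination_index(0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            metrics.discrimination_index(-1.0, 2.0)


class TestWindows:
    def test_test_window_from_first_interaction(self):
        sched = short_schedule()
        n = int(sched.total_duration_s * 2)
        start_frame = int((sched.phase("test").start_s + 85.0) * 2)
        series = make_series(n, true_frames_left=[start_frame, start_frame + 1])
        windows = metrics.analysis_windows(sched, series)
        t0 = sched.phase("test").start_s
        assert windows["test"] == (t0 + 85.0, min(t0 + 85.0 + 1200.0, sched.phase("test").end_s))
        assert windows["sample"] == (sched.phase("sample").start_s, sched.phase("sample").end_s)

    def test_no_test_exploration_flags_window(self):
        sched = short_schedule()
        series = make_series(int(sched.total_duration_s * 2))
        assert metrics.analysis_windows(sched, series)["test"] is None

    def test_window_clipped_at_phase_end(self):
        sched = short_schedule()
        test = sched.phase("test")
        frame = int((test.end_s - 100.0) * 2)
        series = make_series(int(sched.total_duration_s * 2), true_frames_left=[frame])
        start, end = metrics.analysis_windows(sched, series)["test"]
        assert end == test.end_s
        assert end - start == pytest.approx(100.0)


class TestRelativeDI:
    def test_study_scale_values(self):
        assert metrics.relative_di(0.296, 0.013) == pytest.approx(0.283)

    def test_identical_phases_give_zero(self):
        assert metrics.relative_di(0.4, 0.4) == 0.0

    def test_extreme_bound(self):
        assert metrics.relative_di(1.0, -1.0) == 2.0

    def test_nan_propagates(self):
        assert np.isnan(metrics.relative_di(float("nan"), 0.1))

    def test_side_bias_cancels_in_expectation(self):
        # multiplying one side's exploration in both phases shifts each
        # phase DI but leaves the paired difference near zero
        sched = short_schedule("left")
        n = int(sched.total_duration_s * 2)
        rng = np.random.default_rng(5)
        rel = []
        for _ in range(30):
            left = rng.random(n) < 0.02
            right = (rng.random(n) < 0.02 * 2.5) & ~left  # strong right bias
            series = ExplorationSeries(left, right)
            card = metrics.score_session(series, sched)
            rel.append(card["relative_di"])
        rel = np.asarray(rel)
        assert abs(np.nanmean(rel)) <= 3 * np.nanstd(rel, ddof=1) / np.sqrt(len(rel))


class TestLatencyPeakApproach:
    def test_latency_from_phase_start(self):
        sched = short_schedule()
        frame = int((sched.phase("sample").start_s + 30.0) * 2)
        series = make_series(int(sched.total_duration_s * 2), true_frames_left=[frame])
        binned = metrics.bin_series(series)
        lat, peak = metrics.latency_and_peak(binned, series, sched, "sample")
        assert lat == pytest.approx(30.0)
        assert peak == pytest.approx(0.5)

    def test_no_exploration_flags_latency(self):
        sched = short_schedule()
        series = make_series(int(sched.total_duration_s * 2))
        lat, peak = metrics.latency_and_peak(metrics.bin_series(series), series, sched, "test")
        assert np.isnan(lat) and peak == 0.0

    def test_sample_peak_exceeds_retention_peak(self):
        cfg = short_config(seed=21)
        sessions = simulate_cohort(cfg, 8)
        binned = [metrics.bin_series(s.labels) for s in sessions]
        sched = sessions[0].schedule
        sample_vals = metrics.cohort_peak_values(binned, sched, "sample")
        ret_vals = metrics.cohort_peak_values(binned, sched, "retention")
        assert sample_vals.mean() > ret_vals.mean()

    def test_first_approach_side_mapping(self):
        sched = short_schedule("right")
        frame = int(sched.phase("test").start_s * 2) + 10
        series = make_series(int(sched.total_duration_s * 2), true_frames_right=[frame])
        assert metrics.first_approach(series, sched) == "novel"

    def test_cohort_proportion_and_exact_binomial(self):
        approaches = ["novel"] * 14 + ["familiar"] * 6
        prop, res, k, n = metrics.first_approach_cohort(approaches)
        assert (k, n) == (14, 20)
        assert prop == pytest.approx(0.700)
        # independent tail sums: 15/19 and 10/20 one-sided
        assert stats.exact_binomial(15, 19).pvalue == pytest.approx(5036 / 524288)
        assert stats.exact_binomial(10, 20).pvalue == pytest.approx(0.5 + 184756 / 2**21)


class TestCorrelation:
    def test_collinear_points(self):
        res = stats.pearson([1, 2, 3], [2, 4, 6])
        assert res.statistic == pytest.approx(1.0)

    def test_encode_fast_mice_give_negative_correlation(self):
        # construct cohort records with induced negative dependence: mice that
        # explore the future-novel side longer in the sample recognise worse
        rng = np.random.default_rng(11)
        encode_speed = rng.random(25)
        cohort = pd.DataFrame(
            {
                "sample_t_novel_s": 200 - 150 * encode_speed + rng.normal(0, 10, 25),
                "sample_t_familiar_s": rng.normal(120, 20, 25),
                "relative_di": 0.1 + 0.4 * encode_speed + rng.normal(0, 0.05, 25),
            }
        )
        res = metrics.sample_vs_relative_di_correlation(cohort, at="novel")
        assert res.statistic < 0 and res.pvalue < 0.05

    def test_zero_variance_flagged(self):
        cohort = pd.DataFrame(
            {"sample_t_novel_s": [1.0, 1.0, 1.0], "relative_di": [0.1, 0.2, 0.3]}
        )
        assert not metrics.sample_vs_relative_di_correlation(cohort).ok


class TestStatsSuite:
    def test_paired_t_closed_form(self):
        res = stats.paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(2 * np.sqrt(3), abs=1e-6)
        assert res.df == 2

    def test_bh_step_up(self):
        adj = stats.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_three_way_anova_isolates_active_factor(self):
        # balanced 2x2x2 with variance only along 'facility'
        rows = []
        for fac in ("A", "B"):
            for obj in ("wood", "metal"):
                for side in ("left", "right"):
                    for rep in range(5):
                        rows.append(
                            {
                                "facility": fac,
                                "object": obj,
                                "side": side,
                                "exploration_s": (10.0 if fac == "A" else 20.0) + 0.01 * rep,
                            }
                        )
        table = stats.three_way_anova(pd.DataFrame(rows))
        f_fac = table.loc["C(facility)", "F"]
        others = [table.loc[r, "F"] for r in table.index
                  if r not in ("C(facility)", "Residual")]
        assert f_fac > 100 * max(others)

    def test_degenerate_inputs_flagged(self):
        assert not stats.one_sample_t([1.0, 1.0, 1.0], 0.5).ok
        assert not stats.paired_t([1.0], [2.0]).ok
        assert not stats.shapiro_wilk([1.0, 2.0]).ok
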