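import numpy as np
import pytest
from scipy import stats

import pollenclim as pc
from pollenclim.io_formats import ValidationError


def series(start, values, variable="feb_mean_temp"):
    return pc.InstrumentalSeries(variable, start, np.asarray(values, dtype=float))


class TestAlignToIntervals:
    def test_one_year_interval_is_identity(self):
        s = series(1820, [1.0, 2.0, 3.0])
        rec = pc.ReconstructionSeries([(1821, 1821)], [9.9])
        _, instr, _ = pc.align_to_intervals(s, rec)
        assert instr[0] == pytest.approx(2.0)

    def test_four_year_interval_mean(self):
        s = series(1820, [1.0, 2.0, 3.0, 4.0])
        rec = pc.ReconstructionSeries([(1820, 1823)], [0.0])
        _, instr, _ = pc.align_to_intervals(s, rec)
        assert instr[0] == pytest.approx(2.5)

    def test_partial_overlap_dropped(self):
        # 15 four-year samples over 1820-1879 against a series to 1876:
        # the last sample (1876-1879) is clipped away, 14 retained
        s = series(1820, np.arange(57, dtype=float))  # 1820..1876
        intervals = [(1820 + 4 * i, 1823 + 4 * i) for i in range(15)]
        rec = pc.ReconstructionSeries(intervals, np.zeros(15))
        rec_vals, instr, kept = pc.align_to_intervals(s, rec)
        assert len(kept) == 14
        assert kept[-1] == (1872, 1875)

    def test_no_overlap_rejected(self):
        s = series(1900, [1.0, 2.0])
        rec = pc.ReconstructionSeries([(1700, 1703)], [0.0])
        with pytest.raises(ValidationError, match="no samples"):
            pc.align_to_intervals(s, rec)

    def test_coverage_weighted_mean_conserved(self):
        rng = np.random.default_rng(8)
        vals = rng.normal(size=40)
        s = series(1800, vals)
        intervals = [(1800 + 4 * i, 1803 + 4 * i) for i in range(10)]
        rec = pc.ReconstructionSeries(intervals, np.zeros(10))
        _, instr, _ = pc.align_to_intervals(s, rec)
        # equal-length full-coverage intervals: mean of means = annual mean
        assert instr.mean() == pytest.approx(vals.mean(), abs=1e-12)


class TestWelchT:
    def test_identical_groups_give_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = pc.welch_t_test(a, a.copy())
        assert rep.statistic == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_value(self):
        rep = pc.welch_t_test([0.0, 1.0, 2.0], [10.0, 11.0, 12.0])
        # means 1 and 11, both variances 1: t = -10 / sqrt(2/3)
        assert rep.statistic == pytest.approx(-10.0 / np.sqrt(2.0 / 3.0), abs=1e-10)
        assert rep.df == pytest.approx(4.0, abs=1e-10)

    def test_satterthwaite_df_behaviour(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0, 1, 15)
        equal = pc.welch_t_test(a, b)
        assert 20 < equal.df <= 28  # near the pooled 28 when variances agree
        c = rng.normal(0, 20, 15)
        unequal = pc.welch_t_test(c, b)
        assert unequal.df < 16  # collapses toward the noisier group's n - 1

    def test_pooled_variant(self):
        a = [0.0, 1.0, 2.0]
        b = [10.0, 11.0, 12.0, 13.0]
        rep = pc.welch_t_test(a, b, equal_var=True)
        ref_t, ref_p = stats.ttest_ind(a, b, equal_var=True)
        assert rep.statistic == pytest.approx(ref_t, rel=1e-12)
        assert rep.p_value == pytest.approx(ref_p, rel=1e-12)
        assert rep.df == 5

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            pc.welch_t_test([1.0], [1.0, 2.0])


class TestVarianceF:
    def test_identity(self):
        a = np.array([1.0, 2.0, 4.0])
        rep = pc.variance_f_test(a, a.copy())
        assert rep.statistic == pytest.approx(1.0)

    @pytest.mark.parametrize("sd_a,sd_b,expected", [
        (0.38, 2.17, 0.031),
        (0.28, 2.17, 0.017),
    ])
    def test_summary_inputs(self, sd_a, sd_b, expected):
        rep = pc.variance_f_test_from_summary(sd_a, sd_b, 14, 14)
        assert rep.statistic == pytest.approx(expected, abs=5e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pc.variance_f_test([1.0, 2.0], [3.0, 3.0])


class TestPairedT:
    def test_zero_differences(self):
        rep = pc.paired_t_test([0.0, 0.0, 0.0])
        assert rep.statistic == 0.0

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(10)
        rep = pc.paired_t_test(rng.normal(size=133))
        assert rep.df == 132

    def test_hand_computed_value(self):
        rep = pc.paired_t_test([1.0, 2.0, 3.0])
        assert rep.statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), abs=1e-10)


class TestOlsTrend:
    def test_perfectly_linear_series(self):
        rep = pc.ols_trend(series(1, [2.0, 4.0, 6.0, 8.0, 10.0], "v"))
        assert rep.mean_a == pytest.approx(2.0, abs=1e-12)   # slope
        assert rep.mean_b == pytest.approx(8.0, abs=1e-12)   # total change
        assert rep.p_value == pytest.approx(0.0, abs=1e-12)

    def test_df_is_n_minus_two(self):
        rng = np.random.default_rng(11)
        rep = pc.ols_trend(series(1820, rng.normal(size=193)))
        assert rep.df == 191

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            pc.ols_trend(series(1820, [1.0, 2.0]))


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(pc.moving_average(np.full(8, 3.3)),
                                   np.full(8, 3.3))

    def test_center_value(self):
        out = pc.moving_average([1.0, 2.0, 3.0, 4.0, 5.0], window=5)
        assert out[2] == pytest.approx(3.0)
        assert out[0] == pytest.approx(2.0)  # truncated to 1..3

    def test_smoothing_reduces_variance(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=300)
        assert pc.moving_average(x).var() <= x.var()

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            pc.moving_average([1.0, 2.0, 3.0], window=4)


class TestPeriodMean:
    def test_single_sample(self):
        rec = pc.ReconstructionSeries([(1800, 1803)], [-11.4])
        assert pc.period_mean(rec, 1700, 1900) == pytest.approx(-11.4)

    def test_two_samples(self):
        rec = pc.ReconstructionSeries([(1800, 1803), (1804, 1807)], [-12.0, -10.0])
        assert pc.period_mean(rec, 1700, 1900) == pytest.approx(-11.0)

    def test_empty_period_rejected(self):
        rec = pc.ReconstructionSeries([(1800, 1803)], [1.0])
        with pytest.raises(ValidationError):
            pc.period_mean(rec, 1900, 1950)


class TestVarianceCaptured:
    def test_identity_is_100(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=20)
        assert pc.variance_captured(x, x.copy()) == pytest.approx(100.0)

    def test_constant_reconstruction_is_0(self):
        rng = np.random.default_rng(14)
        assert pc.variance_captured(np.full(10, 5.0), rng.normal(size=10)) == 0.0

    def test_attenuated_sd_ratio(self):
        # sd ratio 0.38 / 2.17 corresponds to ~3.1% variance retained
        rng = np.random.default_rng(15)
        z = rng.normal(size=5000)
        pct = pc.variance_captured(0.38 * z, 2.17 * z)
        assert pct == pytest.approx(100 * (0.38 / 2.17) ** 2, rel=1e-9)
        assert pct == pytest.approx(3.1, abs=0.05)


class TestExtendSeriesByRegression:
    def test_self_extension_is_identity(self):
        rng = np.random.default_rng(16)
        s = series(1900, rng.normal(size=30))
        ext, r2 = pc.extend_series_by_regression(s, s)
        assert r2 == pytest.approx(1.0)
        np.testing.assert_allclose(ext.values, s.values, atol=1e-10)

    def test_noise_free_linear_recovery(self):
        rng = np.random.default_rng(17)
        ref = series(1820, rng.normal(size=60), "ref")
        target = pc.InstrumentalSeries("tgt", 1850, 2.0 * ref.values[30:] + 1.0)
        ext, r2 = pc.extend_series_by_regression(target, ref)
        assert r2 == pytest.approx(1.0)
        np.testing.assert_allclose(ext.window(1820, 1849),
                                   2.0 * ref.values[:30] + 1.0, atol=1e-8)
        # observed years kept verbatim
        np.testing.assert_array_equal(ext.window(1850, 1879), target.values)

    def test_noisy_fill_error_consistent_with_residual_sd(self):
        rng = np.random.default_rng(18)
        n = 200
        ref_vals = rng.normal(0, 2.0, size=n)
        noise_sd = 0.65  # high shared signal: r²_adj well above 0.9
        tgt_full = 1.5 * ref_vals + rng.normal(0, noise_sd, size=n)
        ref = series(1800, ref_vals, "ref")
        target = pc.InstrumentalSeries("tgt", 1800 + n // 2, tgt_full[n // 2:])
        ext, r2 = pc.extend_series_by_regression(target, ref)
        assert 0.8 < r2 < 0.98
        fill_rmse = np.sqrt(np.mean(
            (ext.values[: n // 2] - tgt_full[: n // 2]) ** 2))
        assert fill_rmse == pytest.approx(noise_sd, rel=0.35)

    def test_insufficient_overlap_rejected(self):
        ref = series(1800, np.arange(20, dtype=float), "ref")
        target = pc.InstrumentalSeries("tgt", 1815, np.arange(10, dtype=float))
        with pytest.raises(ValidationError, match="overlap"):
            pc.extend_series_by_regression(target, ref)


class TestFullPipelineHeadline:
    def test_disturbed_calibration_attenuates_lia_signal(
            self, species_pool, calset_full, modern_set):
        """The conventional-set reconstruction is warm-biased over the
        pre-industrial record relative to the pre-settlement-set one."""
        history = pc.default_history(seed=19)
        fossil, truth = pc.generate_downcore(species_pool, history, seed=19)
        tf_1870 = pc.fit_wapls(calset_full, "feb_mean_temp")
        tf_modern = pc.fit_wapls(modern_set, "feb_mean_temp")
        rec_1870 = pc.ReconstructionSeries(fossil.intervals,
                                           pc.predict(tf_1870, fossil.samples))
        rec_modern = pc.ReconstructionSeries(fossil.intervals,
                                             pc.predict(tf_modern, fossil.samples))
        truth_lia = truth["feb_mean_temp"][
            (fossil.midpoints > 1450) & (fossil.midpoints < 1850)].mean()
        lia_1870 = pc.period_mean(rec_1870, 1450, 1850)
        lia_modern = pc.period_mean(rec_modern, 1450, 1850)
        # conventional (disturbed-modern) reconstruction runs warm
        assert lia_modern > lia_1870
        # and the pre-settlement one is closer to the injected truth
        assert abs(lia_1870 - truth_lia) < abs(lia_modern - truth_lia)
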