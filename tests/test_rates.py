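"""Production-rate fitting and ratio-of-slopes statistics."""

import numpy as np
import pytest

from thermoprobe import rates


class TestFitProductionRate:
    def test_exact_line(self):
        est = rates.fit_production_rate([(0, 0), (2, 1), (4, 2), (8, 4)])
        assert est.slope == pytest.approx(0.5)
        assert est.r_squared == pytest.approx(1.0)

    def test_noisy_line_closed_form(self):
        # frozen against the closed-form OLS solution:
        # slope = Sxy/Sxx = 17.3/35, r^2 = Sxy^2/(Sxx*Syy) = 299.29/299.95
        est = rates.fit_production_rate([(0, 0), (2, 1.1), (4, 1.9), (8, 4.0)])
        assert est.slope == pytest.approx(17.3 / 35, abs=1e-12)
        assert est.r_squared == pytest.approx(17.3**2 / (35 * 8.57), abs=1e-12)

    def test_flat_series(self):
        est = rates.fit_production_rate([(0, 1.0), (2, 1.0), (4, 1.0)],
                                        anchor_t0=False)
        assert est.slope == 0.0

    def test_t0_anchor_added(self):
        est = rates.fit_production_rate([(2, 1), (4, 2), (8, 4)])
        assert est.n_points == 4
        assert est.intercept == pytest.approx(0.0)

    def test_insufficient_data(self):
        with pytest.raises(rates.InsufficientDataError):
            rates.fit_production_rate([(2, 1)], anchor_t0=False)
        with pytest.raises(rates.InsufficientDataError):
            rates.fit_production_rate([(2, 1), (2, 2)], anchor_t0=False)

    def test_slope_recovery_within_3_true_se(self):
        """OLS slope lands within 3 true standard errors of the generating
        rate in >= 95% of 1000 seeded replicates (expected ~99.7%)."""
        rng = np.random.default_rng(42)
        t = np.array([0.0, 2.0, 4.0, 8.0])
        sigma, s_true = 0.01, 0.05
        # anchored t=0 point is exact; propagate noise through the OLS weights
        c = (t - t.mean()) / np.sum((t - t.mean()) ** 2)
        se_true = sigma * np.sqrt(np.sum(c[1:] ** 2))
        hits = 0
        for _ in range(1000):
            y = s_true * t + rng.normal(0, sigma, 4)
            y[0] = 0.0
            est = rates.fit_production_rate(list(zip(t, y)))
            hits += abs(est.slope - s_true) < 3 * se_true
        assert hits / 1000 >= 0.95


class TestRatioOfSlopes:
    def test_triplicates(self):
        rs = rates.ratio_of_slopes([2, 2, 2], [4, 4, 4])
        assert rs.n == 9
        assert rs.mean == pytest.approx(0.5)
        assert rs.sem == 0.0

    def test_enumeration(self):
        rs = rates.ratio_of_slopes([1, 2, 3], [2, 4, 6])
        assert rs.n == 9
        assert rs.mean == pytest.approx(5.5 / 9, abs=1e-12)

    def test_degenerate_single(self):
        rs = rates.ratio_of_slopes([1], [2])
        assert rs.n == 1 and rs.mean == 0.5

    def test_zero_denominator_excluded(self):
        with pytest.warns(UserWarning):
            rs = rates.ratio_of_slopes([1, 2], [2, 0])
        assert rs.n == 2

    def test_mean_converges_to_true_ratio(self):
        rng = np.random.default_rng(0)
        num = 1.0 + rng.normal(0, 1e-6, 3)
        den = 2.0 + rng.normal(0, 1e-6, 3)
        rs = rates.ratio_of_slopes(num, den)
        assert rs.mean == pytest.approx(0.5, abs=1e-5)


class TestOneSampleT:
    def test_centered_sample(self):
        res = rates.one_sample_t(
            rates.RatioSample("s", "p", np.array([0.4, 0.5, 0.6]), 0.5, 0.0),
            0.5)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_values(self):
        res = rates.one_sample_t(
            rates.RatioSample("s", "p", np.array([0.6, 0.7, 0.8]), 0.7, 0.0),
            0.5)
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.0742, abs=2e-4)

    def test_zero_variance_flag(self):
        res = rates.one_sample_t(
            rates.RatioSample("s", "p", np.array([0.5, 0.5, 0.5]), 0.5, 0.0),
            0.4)
        assert np.isnan(res.statistic)
        assert "undefined" in res.note


class TestCompareSites:
    def test_identical_groups_share_letter(self):
        groups = {"a": np.array([1.0, 1.1, 0.9]),
                  "b": np.array([1.0, 1.1, 0.9]),
                  "c": np.array([1.0, 1.1, 0.9])}
        cmp = rates.compare_sites(groups)
        assert cmp.anova.statistic == pytest.approx(0.0, abs=1e-12)
        assert len(set(cmp.letters.values())) == 1

    def test_outlier_group_distinct(self):
        groups = {"g1": [1, 1.1, 0.9], "g2": [5, 5.1, 4.9],
                  "g3": [1, 1.05, 0.95]}
        cmp = rates.compare_sites(groups)
        letters = cmp.letters
        assert set(letters["g1"]) & set(letters["g3"])
        assert not set(letters["g2"]) & set(letters["g1"])
        assert cmp.anova.p_value < 1e-4

    def test_two_groups_tukey_equals_anova(self):
        groups = {"a": [1.0, 1.2, 0.8, 1.1], "b": [1.5, 1.6, 1.4, 1.7]}
        cmp = rates.compare_sites(groups)
        assert cmp.tukey[0].p_value == pytest.approx(cmp.anova.p_value,
                                                     abs=1e-6)

    def test_welch_reported_per_pair(self):
        groups = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [10, 11, 12]}
        cmp = rates.compare_sites(groups)
        assert len(cmp.welch) == 3
        assert all(0 <= t.p_value <= 1 for t in cmp.welch)

    def test_too_few_groups(self):
        with pytest.raises(rates.InsufficientDataError):
            rates.compare_sites({"a": [1, 2]})


class TestControlSummary:
    def test_clean_controls(self):
        df = rates.control_summary([1.0, 1.1], {"poisoned-glut": [0.0, 0.0]})
        assert df.loc[0, "flag"] == "clean"
        assert np.isinf(df.loc[0, "live_control_ratio"])

    def test_abiotic_dominated(self):
        df = rates.control_summary([1.0], {"poisoned-Hg": [1.0]})
        assert df.loc[0, "flag"] == "abiotic-dominated"
        assert df.loc[0, "live_control_ratio"] == pytest.approx(1.0)

    def test_ratio_arithmetic(self):
        df = rates.control_summary([1.0], {"poisoned-glut": [0.1]})
        assert df.loc[0, "live_control_ratio"] == pytest.approx(10.0)

    def test_subtract_option(self):
        df = rates.control_summary([1.0], {"poisoned-glut": [0.1]},
                                   subtract=True)
        assert df.loc[0, "live_mean_slope"] == pytest.approx(0.9)


class TestBootstrap:
    def test_runs_and_bounded(self):
        rng = np.random.default_rng(5)
        num = 1.0 + rng.normal(0, 0.05, 3)
        den = 2.0 + rng.normal(0, 0.05, 3)
        res = rates.bootstrap_ratio_test(num, den, 0.5, n_boot=500, seed=1)
        assert 0.0 <= res.p_value <= 1.0

    def test_detects_large_shift(self):
        res = rates.bootstrap_ratio_test([1.0, 1.01, 0.99], [1.0, 1.01, 0.99],
                                         5.0, n_boot=500, seed=1)
        assert res.p_value < 0.05


def test_annotation_convention():
    assert rates.annotate_significance(0.5) == ""
    assert rates.annotate_significance(5e-4) == "*"
    assert rates.annotate_significance(5e-5) == "**"
    assert rates.annotate_significance(5e-6) == "***"
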