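"""Disparity statistics: rank tests, fixed-effects models, concentration."""

import math

import numpy as np
import pandas as pd
import pytest

from coastrisk.equity import (
    compare_exposed_unexposed,
    concentration_ci,
    concentration_curve,
    concentration_index,
    fit_exposure_model,
    standardize,
)
from coastrisk.synth import simulate_exposure_covariates


def brute_force_concentration(rank_values, burdens):
    """Gini-covariance double-sum form on descending ranks:
    C = (2/n) * sum_i s_i * (i - (n+1)/2) with i the 1-based position in
    descending rank order and s_i the burden share."""
    order = np.argsort(-np.asarray(rank_values), kind="stable")
    s = np.asarray(burdens, dtype=float)[order]
    s = s / s.sum()
    n = len(s)
    i = np.arange(1, n + 1)
    return (2.0 / n) * float(np.sum(s * (i - (n + 1) / 2.0)))


class TestCompareGroups:
    def test_identical_distributions_high_p(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=400)
        exposed = pd.Series([True, False] * 200)
        out = compare_exposed_unexposed(exposed, pd.DataFrame({"v": vals}))
        assert out.loc[0, "p_value"] > 0.2

    def test_complete_separation_tiny_p(self):
        exposed = pd.Series([True] * 25 + [False] * 25)
        vals = np.concatenate([np.arange(25) + 100.0, np.arange(25)])
        out = compare_exposed_unexposed(exposed, pd.DataFrame({"v": vals}))
        assert out.loc[0, "p_value"] < 0.001
        assert out.loc[0, "exposed_median"] > out.loc[0, "unexposed_median"]

    def test_constant_covariate_all_ties(self):
        exposed = pd.Series([True] * 10 + [False] * 10)
        out = compare_exposed_unexposed(exposed, pd.DataFrame({"v": np.ones(20)}))
        assert out.loc[0, "p_value"] == 1.0

    def test_needs_both_groups(self):
        with pytest.raises(ValueError):
            compare_exposed_unexposed(pd.Series([True, True]), pd.DataFrame({"v": [1, 2]}))


class TestStandardize:
    def test_zscore_algebra(self):
        df = pd.DataFrame({"v": [0.2, 0.3, 0.4]})  # mean .3, sd(pop) ~ .0816
        z = standardize(df)
        assert z["v"].iloc[2] == pytest.approx((0.4 - 0.3) / df["v"].std(ddof=0))
        assert z["v"].mean() == pytest.approx(0.0, abs=1e-12)
        assert z["v"].std(ddof=0) == pytest.approx(1.0)

    def test_binary_flag_untouched(self):
        df = pd.DataFrame({"cejst_disadvantaged": [0, 1, 1, 0], "v": [1.0, 2, 3, 4]})
        z = standardize(df)
        assert set(z["cejst_disadvantaged"]) == {0, 1}

    def test_zero_variance_named(self):
        with pytest.raises(ValueError, match="flat"):
            standardize(pd.DataFrame({"flat": [1.0, 1.0, 1.0]}))

    def test_destandardized_coefficient_matches_raw_fit(self):
        # beta from the z-scored fit divided by the covariate SD equals the
        # coefficient of the unstandardized fit
        rng = np.random.default_rng(8)
        n = 1500
        x = rng.normal(0.3, 0.07, size=n)
        county = rng.integers(0, 5, size=n)
        y = 2.0 * x + 0.1 * county + rng.normal(0, 0.2, size=n)
        z = standardize(pd.DataFrame({"x": x}))["x"]
        est_z = fit_exposure_model(y, z, np.zeros(n), county, "linear")
        est_raw = fit_exposure_model(y, x, np.zeros(n), county, "linear")
        sd = x.std(ddof=0)
        assert est_z.estimate / sd == pytest.approx(est_raw.estimate, rel=1e-8)


class TestExposureModels:
    def test_logistic_2x2_matches_cross_product_ratio(self):
        """With a binary covariate, no density effect, and two balanced
        counties, exp(beta) equals the pooled cross-product odds ratio."""
        # identical 2x2 table in each county: a=30 b=20 / c=10 d=40
        y, x, county = [], [], []
        for cty in (0, 1):
            for yy, xx, n in ((1, 1, 30), (0, 1, 20), (1, 0, 10), (0, 0, 40)):
                y += [yy] * n
                x += [xx] * n
                county += [cty] * n
        est = fit_exposure_model(y, x, np.zeros(len(y)), county, "logistic")
        assert est.estimate == pytest.approx((30 * 40) / (20 * 10), rel=1e-4)

    def test_null_covariate_or_near_one(self):
        df = simulate_exposure_covariates(3000, 10, 0.0, seed=7)
        noise = np.random.default_rng(1).normal(size=len(df))
        est = fit_exposure_model(df["exposed"], noise, df["density_z"], df["county"], "logistic")
        assert est.ci_low < 1.0 < est.ci_high

    def test_negative_binomial_recovers_positive_count_slope(self):
        df = simulate_exposure_covariates(4000, 10, math.log(1.6), seed=3)
        sub = df[df["exposed"] == 1]
        est = fit_exposure_model(sub["n_sites"], sub["x"], sub["density_z"], sub["county"], "negative_binomial")
        assert est.measure == "IRR" and est.estimate > 1.0

    def test_linear_mean_difference(self):
        rng = np.random.default_rng(5)
        n = 2000
        x = rng.normal(size=n)
        county = rng.integers(0, 8, size=n)
        y = 0.15 * x + 0.05 * county + rng.normal(0, 0.3, size=n)
        est = fit_exposure_model(y, x, np.zeros(n), county, "linear")
        assert est.measure == "mean_difference"
        assert est.estimate == pytest.approx(0.15, abs=0.03)
        assert est.ci_low <= 0.15 <= est.ci_high

    def test_degenerate_counties_dropped_from_logistic(self):
        df = simulate_exposure_covariates(800, 6, 0.3, seed=9)
        df.loc[df["county"] == 0, "exposed"] = 1  # county 0 has no variation
        est = fit_exposure_model(df["exposed"], df["x"], df["density_z"], df["county"], "logistic")
        assert est.n_counties_dropped >= 1
        assert est.n_counties <= 5

    def test_single_county_rejected(self):
        with pytest.raises(ValueError, match="counties"):
            fit_exposure_model([0, 1, 0, 1], [0.0, 1, 0, 1], np.zeros(4), ["A"] * 4, "logistic")


class TestConcentration:
    def test_equal_burden_gives_diagonal_and_zero_index(self):
        curve = concentration_curve(np.arange(10)[::-1], np.ones(10))
        assert np.allclose(curve[:, 0], curve[:, 1])
        assert concentration_index(curve) == pytest.approx(0.0, abs=1e-12)

    def test_all_burden_in_top_ranked_block(self):
        burdens = np.zeros(10)
        burdens[0] = 5.0
        ranks = np.linspace(1, 0, 10)  # block 0 most marginalized
        curve = concentration_curve(ranks, burdens)
        # curve passes (0.1, 1.0); area A = 0.95 -> C = -0.9
        row = curve[np.isclose(curve[:, 0], 0.1)]
        assert row[0, 1] == pytest.approx(1.0)
        assert concentration_index(curve) == pytest.approx(-0.9)

    def test_rank_reversal_flips_sign(self):
        rng = np.random.default_rng(2)
        ranks = rng.random(50)
        burdens = rng.random(50)
        c_fwd = concentration_index(concentration_curve(ranks, burdens))
        c_rev = concentration_index(concentration_curve(-ranks, burdens))
        assert c_rev == pytest.approx(-c_fwd, abs=1e-12)

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(3)
        for n in (5, 12, 20):
            ranks = rng.random(n)
            burdens = rng.integers(0, 6, size=n).astype(float)
            if burdens.sum() == 0:
                burdens[0] = 1.0
            c = concentration_index(concentration_curve(ranks, burdens))
            assert c == pytest.approx(brute_force_concentration(ranks, burdens), abs=1e-9)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(4)
        curve = concentration_curve(rng.random(30), rng.random(30))
        assert np.all(np.diff(curve[:, 0]) >= 0)
        assert np.all(np.diff(curve[:, 1]) >= -1e-15)
        assert curve[0].tolist() == [0.0, 0.0]
        assert curve[-1].tolist() == [1.0, 1.0]

    def test_all_zero_burden_rejected(self):
        with pytest.raises(ValueError):
            concentration_curve(np.arange(10), np.zeros(10))


class TestConcentrationCI:
    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(6)
        ranks, burdens = rng.random(40), rng.random(40)
        a = concentration_ci(ranks, burdens, n_boot=200, seed=5)
        b = concentration_ci(ranks, burdens, n_boot=200, seed=5)
        assert a == b

    def test_equality_data_ci_contains_zero(self):
        ranks = np.linspace(0, 1, 60)
        lo, hi = concentration_ci(ranks, np.ones(60), n_boot=300, seed=1)
        assert lo <= 0.0 <= hi

    def test_extreme_concentration_significant_at_n200(self):
        ranks = np.linspace(1, 0, 200)
        burdens = np.zeros(200)
        burdens[:10] = 1.0  # burden only in the most marginalized decile
        lo, hi = concentration_ci(ranks, burdens, n_boot=500, seed=2)
        assert hi < 0.0

    def test_too_few_bootstraps_rejected(self):
        with pytest.raises(ValueError):
            concentration_ci(np.arange(20), np.ones(20), n_boot=50, seed=0)
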