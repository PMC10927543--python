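"""Trend slopes, summaries and the smoothing-spline curve."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pollentrends.trends import (
    SplineFit,
    abundance_by_settlement,
    fit_trend_spline,
    occupancy_summary,
    pair_slope,
    pair_trend_table,
    site_summary,
)

from conftest import make_samples


class TestPairSlope:
    def test_constant_series_is_flat(self):
        assert pair_slope(
            np.array([4650.0, 4150.0, 3650.0, 3150.0]), np.full(4, 0.3)
        ) == (0.0, "flat")

    def test_collinear_rising_toward_present_is_homogenizing(self):
        slope, cls = pair_slope(
            np.array([4000.0, 3000.0, 2000.0, 1000.0]),
            np.array([0.05, 0.10, 0.15, 0.20]),
        )
        assert slope == pytest.approx(-5e-5)
        assert cls == "homogenizing"

    def test_three_points_dropped(self):
        assert pair_slope(np.array([1.0, 2.0, 3.0]), np.array([0.1, 0.2, 0.3])) is None

    def test_duplicate_ages_rejected(self):
        with pytest.raises(ValueError):
            pair_slope(np.array([1.0, 1.0, 2.0, 3.0]), np.zeros(4))

    @given(
        ys=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=5, max_size=5
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_brute_force_least_squares(self, ys):
        """OLS slope agrees with iterative grid minimization of the SSE."""
        x = np.array([4650.0, 4150.0, 3650.0, 3150.0, 2650.0])
        y = np.array(ys)
        res = pair_slope(x, y)
        assert res is not None
        slope = res[0]

        def sse(b):
            a = y.mean() - b * x.mean()
            return ((y - (a + b * x)) ** 2).sum()

        lo, hi = -1e-2, 1e-2
        for _ in range(60):  # nested grid refinement, independent of OLS algebra
            grid = np.linspace(lo, hi, 41)
            j = int(np.argmin([sse(b) for b in grid]))
            lo, hi = grid[max(j - 1, 0)], grid[min(j + 1, 40)]
        brute = 0.5 * (lo + hi)
        assert slope == pytest.approx(brute, abs=1e-8)

    def test_time_axis_reversal_flips_every_slope(self, rng):
        x = np.array([4650.0, 4150.0, 3650.0, 3150.0, 2650.0])
        for _ in range(20):
            y = rng.uniform(0, 1, x.size)
            s_fwd = pair_slope(x, y)
            s_rev = pair_slope(-x, y)
            assert s_fwd[0] == pytest.approx(-s_rev[0])
            flip = {"homogenizing": "differentiating",
                    "differentiating": "homogenizing", "flat": "flat"}
            assert s_rev[1] == flip[s_fwd[1]]


class TestPairTrendTable:
    def test_short_pairs_dropped_long_pairs_kept(self):
        rows = []
        for age in (4650.0, 4150.0, 3650.0, 3150.0):
            rows.append(("S1", "S2", age, 0.5))
        for age in (4650.0, 4150.0, 3650.0):
            rows.append(("S1", "S3", age, 0.5))
        comp = pd.DataFrame(rows, columns=["site_a", "site_b", "age_mid", "similarity"])
        out = pair_trend_table(comp)
        assert out[["site_a", "site_b"]].values.tolist() == [["S1", "S2"]]
        assert out.iloc[0]["n_points"] == 4


class TestSummaries:
    def test_site_proportion_and_median(self):
        trends = pd.DataFrame(
            {
                "site_a": ["S1", "S1", "S1"],
                "site_b": ["S2", "S3", "S4"],
                "slope": [-1e-5, -2e-5, 3e-5],
                "n_points": [5, 5, 5],
                "classification": ["homogenizing", "homogenizing", "differentiating"],
            }
        )
        out = site_summary(trends, ["S1"]).iloc[0]
        assert out["n_pairs"] == 3
        assert out["proportion_homogenizing"] == pytest.approx(2 / 3)
        assert out["median_slope"] == pytest.approx(-1e-5)

    def test_all_negative_gives_proportion_one(self):
        trends = pd.DataFrame(
            {"site_a": ["S1"] * 4, "site_b": list("abcd"),
             "slope": [-1e-5] * 4, "n_points": [4] * 4,
             "classification": ["homogenizing"] * 4}
        )
        assert site_summary(trends, ["S1"]).iloc[0]["proportion_homogenizing"] == 1.0

    def test_quartile_invariant(self):
        trends = pd.DataFrame(
            {"site_a": ["S1"] * 5, "site_b": list("abcde"),
             "slope": [-3e-5, -1e-5, 0.0, 2e-5, 4e-5], "n_points": [4] * 5,
             "classification": ["homogenizing"] * 2 + ["flat"] + ["differentiating"] * 2}
        )
        row = site_summary(trends, ["S1"]).iloc[0]
        assert row["q1_slope"] <= row["median_slope"] <= row["q3_slope"]
        assert row["min_slope"] <= row["q1_slope"]
        assert row["q3_slope"] <= row["max_slope"]

    def test_occupancy_three_point_quartiles(self):
        comp = pd.DataFrame(
            {"occupancy": ["both"] * 3, "similarity": [0.2, 0.4, 0.6]}
        )
        out = occupancy_summary(comp).set_index("occupancy")
        assert out.loc["both", "n"] == 3
        assert out.loc["both", "median"] == pytest.approx(0.4)
        assert out.loc["both", "q1"] == pytest.approx(0.3)
        assert out.loc["both", "q3"] == pytest.approx(0.5)
        assert out.loc["neither", "n"] == 0 and out.loc["one", "n"] == 0

    def test_tukey_whiskers_clip_outliers(self):
        vals = [0.1, 0.11, 0.12, 0.13, 0.14, 0.9]
        comp = pd.DataFrame({"occupancy": ["one"] * 6, "similarity": vals})
        row = occupancy_summary(comp).set_index("occupancy").loc["one"]
        assert row["whisker_high"] == pytest.approx(0.14)  # 0.9 is outside 1.5*IQR
        assert row["whisker_low"] == pytest.approx(0.1)


class TestSpline:
    def test_noiseless_collinear_reproduced(self):
        x = np.linspace(0.0, 10.0, 15)
        y = 0.2 + 0.03 * x
        fit = fit_trend_spline(x, y)
        assert np.abs(fit.fit - (0.2 + 0.03 * fit.grid)).max() < 1e-6

    def test_constant_input_constant_fit(self):
        x = np.linspace(0.0, 10.0, 12)
        fit = fit_trend_spline(x, np.full(12, 0.4))
        assert np.abs(fit.fit - 0.4).max() < 1e-9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_trend_spline(np.ones(12), np.linspace(0, 1, 12))
        with pytest.raises(ValueError):
            fit_trend_spline(np.arange(5.0), np.arange(5.0))

    def test_ci_brackets_fit_pointwise(self, rng):
        x = rng.uniform(0, 5000, 60)
        y = 0.1 + 0.00002 * x + rng.normal(0, 0.02, 60)
        fit = fit_trend_spline(x, y)
        assert (fit.ci_low <= fit.fit).all()
        assert (fit.fit <= fit.ci_high).all()
        assert fit.sigma2 > 0

    def test_large_penalty_limit_is_the_ols_line(self):
        from scipy.interpolate import make_smoothing_spline
        from scipy.stats import linregress

        rng = np.random.default_rng(3)
        x = np.sort(rng.uniform(0.0, 10.0, 40))
        y = 0.3 + 0.05 * x + rng.normal(0, 0.05, 40)
        big = make_smoothing_spline(x, y, lam=1e6)
        reg = linregress(x, y)
        line = reg.intercept + reg.slope * x
        assert np.abs(big(x) - line).max() < 1e-4
        # slope-penalized limit shrinks to the data mean at the mean age
        assert big(x.mean()) == pytest.approx(
            reg.intercept + reg.slope * x.mean(), abs=1e-4
        )

    def test_recovers_known_smooth_trend(self):
        rng = np.random.default_rng(99)
        ages = rng.uniform(-100.0, 4900.0, 800)
        truth = 0.07 + 0.10 * (4900.0 - ages) / 4900.0
        y = truth + rng.normal(0.0, 0.02, ages.size)
        fit = fit_trend_spline(ages, y)
        grid_truth = 0.07 + 0.10 * (4900.0 - fit.grid) / 4900.0
        assert np.abs(fit.fit - grid_truth).max() < 0.01


class TestAbundanceBySettlement:
    def test_single_taxon_everywhere(self):
        df = make_samples(
            [("S1", 4000.0, "A", 50.0, "counts"), ("S1", 100.0, "A", 80.0, "counts")]
        )
        out = abundance_by_settlement(df, {"S1": "I1"}, {"I1": 700.0})
        row = out.set_index("taxon").loc["A"]
        assert row["mean_pct_pre"] == pytest.approx(100.0)
        assert row["mean_pct_post"] == pytest.approx(100.0)

    def test_disturbance_taxa_rank_top_post_settlement(self, default_archipelago):
        site_meta, settlements, name_table, samples, truth = default_archipelago
        from pollentrends.taxonomy import removable_raw_names, standardize

        known = samples.loc[
            ~samples["taxon"].isin(removable_raw_names(name_table))
        ]
        std = standardize(known, name_table, "std1")
        settle = dict(zip(settlements["island_id"], settlements["settlement_age_bp"]))
        out = abundance_by_settlement(
            std, site_meta.set_index("site_id")["island_id"], settle
        )
        assert set(out["taxon"].head(2)) == set(truth.disturbance_taxa)
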