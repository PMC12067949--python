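"""Post-hoc analyses: delta-J, dose-response fits, climate-deviation tests,
Moran's I and the weighted local clustering coefficient."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import larvopt as lv
from larvopt.stats import fit_dose_response, local_clustering, morans_i

TABLE_POINTS = {
    # budget fractions 0.25/0.50/0.75/1.0 -> published percentage reductions
    "routine_avg": [-24.90, -54.37, -82.95, -99.38],
    "routine_best": [-31.30, -65.81, -92.06, -100.0],
    "optimized": [-70.19, -92.84, -99.69, -100.0],
}
FRACTIONS = [0.25, 0.50, 0.75, 1.0]


class TestDeltaJ:
    def test_reference_values(self):
        assert lv.delta_J(5.0, 5.0) == 0.0
        assert lv.delta_J(0.0, 5.0) == -100.0
        assert lv.delta_J(0.2977 * 7.0, 7.0) == pytest.approx(-70.23)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            lv.delta_J(1.0, 0.0)

    @given(st.floats(1e-6, 1e6), st.floats(0, 2), st.floats(1e-6, 1e6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_invariance(self, J0, ratio, scale):
        a = lv.delta_J(ratio * J0, J0)
        b = lv.delta_J(scale * ratio * J0, scale * J0)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-9)


class TestDoseResponse:
    @pytest.mark.parametrize("row,expected_r2", [
        ("routine_avg", 0.992), ("routine_best", 0.963), ("optimized", 0.734),
    ])
    def test_linear_r2_of_published_reduction_curves(self, row, expected_r2):
        fit = fit_dose_response(FRACTIONS, TABLE_POINTS[row])
        assert fit.linear_r2 == pytest.approx(expected_r2, abs=1e-3)

    def test_collinear_points_prefer_linear(self):
        # exactly collinear points through the origin: linear R^2 = 1, lower AIC
        c = [0.25, 0.5, 0.75, 1.0]
        fit = fit_dose_response(c, [-40.0 * x for x in c])
        assert fit.linear_r2 == pytest.approx(1.0)
        assert fit.linear_aic < fit.exp_aic
        assert fit.better_model == "linear"

    def test_origin_anchor_included_once(self):
        fit = fit_dose_response([0.0] + FRACTIONS, [0.0] + TABLE_POINTS["optimized"])
        assert fit.c.size == 5

    def test_saturating_curve_prefers_exponential(self):
        c = np.array(FRACTIONS)
        dJ = -100 * (1 - np.exp(-4.0 * c))
        fit = fit_dose_response(c, dJ)
        assert fit.better_model == "exponential"
        assert fit.exp_r2 > 0.999

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([0.5, 0.5, 0.5], [-10, -20, -30])


class TestClimateDeviation:
    def test_driest_day_treatments_highly_significant(self, weather_std, params):
        lo, hi = params.season_days(weather_std)
        r21 = weather_std.r21[lo:hi + 1]
        driest = lo + np.argsort(r21)[:10]
        rep = lv.climate_deviation_test(driest.astype(float), weather_std, "r21",
                                        params)
        assert rep.pvalue < 0.01
        assert np.all(rep.deviations <= np.median(rep.background))
        # permutation oracle on the same data agrees on strong significance
        perm = lv.climate_deviation_test(driest.astype(float), weather_std, "r21",
                                         params, method="permutation", seed=1)
        assert perm.pvalue < 0.01

    def test_zero_deviation_sample_gives_p_one(self, params):
        import pandas as pd

        from larvopt.environment import WeatherSeries
        n = 365
        dates = pd.date_range("2021-01-01", periods=n)
        # constant rainfall: every in-season deviation is exactly zero, so the
        # treatment-time sample sits on the background median (no signal)
        w = WeatherSeries(dates, np.full(n, 10.0), np.full(n, 20.0), np.full(n, 4.0))
        lo, _ = params.season_days(w)
        days = np.arange(lo + 5, lo + 9, dtype=float)
        rep = lv.climate_deviation_test(days, w, "r21", params)
        assert rep.pvalue == 1.0
        np.testing.assert_allclose(rep.deviations, 0.0)

    def test_temperature_uses_daily_midpoint(self, weather_std, params):
        lo, hi = params.season_days(weather_std)
        days = np.arange(lo + 30, lo + 40, dtype=float)
        rep = lv.climate_deviation_test(days, weather_std, "temperature", params)
        mid = weather_std.tmid[lo:hi + 1]
        expect = 100 * (mid[days.astype(int) - lo] - mid.mean()) / mid.mean()
        np.testing.assert_allclose(rep.deviations, expect)

    def test_mid_season_split(self, weather_std, params):
        lo, hi = params.season_days(weather_std)
        split = weather_std.day_index("2021-07-15")
        days = np.array([lo + 10.0, split - 1.0, split + 20.0, hi - 5.0])
        rep = lv.climate_deviation_test(days, weather_std, "r21", params)
        assert rep.early.size == 2 and rep.late.size == 2

    def test_unknown_variable_rejected(self, weather_std):
        with pytest.raises(ValueError):
            lv.climate_deviation_test([120.0], weather_std, "humidity")


class TestMoransI:
    def test_expected_value_under_null(self, sites_std):
        vals = np.random.default_rng(0).normal(size=5)
        sites5 = lv.SiteTable(*(arr[:5] for arr in
                                (sites_std.site_id, sites_std.x, sites_std.y,
                                 sites_std.area, sites_std.vmax)))
        res = morans_i(vals, sites5, permutations=99, seed=0)
        assert res.expected == pytest.approx(-0.25)

    def test_clustered_values_detected(self, sites_std):
        res = morans_i(sites_std.x, sites_std, seed=1)
        assert res.I > 0
        assert res.pvalue < 0.01

    def test_alternating_chain_below_expectation(self):
        n = 20
        sites = lv.SiteTable([f"s{i}" for i in range(n)],
                             np.arange(n) * 50.0, np.zeros(n),
                             np.ones(n), np.full(n, 10.0))
        vals = np.tile([1.0, -1.0], n // 2)
        res = morans_i(vals, sites, permutations=99, seed=0)
        assert res.I < res.expected

    def test_constant_values_rejected(self, sites_std):
        with pytest.raises(ValueError):
            morans_i(np.ones(len(sites_std)), sites_std)


class TestLocalClustering:
    def test_equilateral_triangle_symmetric(self):
        h = np.sqrt(3) / 2 * 100
        sites = lv.SiteTable(["a", "b", "c"], [0.0, 100.0, 50.0], [0.0, 0.0, h],
                             [1, 1, 1], [10, 10, 10])
        cc = local_clustering(sites)
        assert np.allclose(cc, cc[0])

    def test_bounded_in_unit_interval(self, sites_std):
        cc = local_clustering(sites_std)
        assert np.all((cc >= 0) & (cc <= 1))

    def test_agrees_with_triple_enumeration(self):
        """Oracle: direct geometric-mean triple enumeration with max-normalized
        inverse-distance weights on 10 random sites."""
        rng = np.random.default_rng(12)
        xy = rng.uniform(0, 300, (10, 2))
        sites = lv.SiteTable([f"s{i}" for i in range(10)], xy[:, 0], xy[:, 1],
                             np.ones(10), np.full(10, 10.0))
        d = sites.distances()
        w = np.zeros_like(d)
        off = ~np.eye(10, dtype=bool)
        w[off] = 1.0 / d[off]
        w_hat = w / w.max()
        n = 10
        brute = np.zeros(n)
        for i in range(n):
            tot = 0.0
            others = [j for j in range(n) if j != i]
            for j, k in itertools.combinations(others, 2):
                tot += (w_hat[i, j] * w_hat[i, k] * w_hat[j, k]) ** (1 / 3)
            deg = n - 1
            brute[i] = 2 * tot / (deg * (deg - 1))
        np.testing.assert_allclose(local_clustering(sites), brute, rtol=1e-10)

    def test_duplicate_coordinates_rejected(self):
        sites = lv.SiteTable(["a", "b", "c"], [0.0, 0.0, 10.0], [0.0, 0.0, 0.0],
                             [1, 1, 1], [10, 10, 10])
        with pytest.raises(ValueError):
            local_clustering(sites)


class TestObservationTable:
    def test_record_count_small(self, sites_small):
        sch = lv.TreatmentSchedule(np.array([91.0, 140.0, 189.0, 238.0]),
                                   np.ones((4, 3), dtype=int), sites_small.dose)
        obs = lv.build_treatment_observations({(2021, 0.25): [sch]}, sites_small)
        assert len(obs) == 3 * 4  # 3 sites x 4 rounds, 1 sim

    def test_full_design_count(self, sites_std):
        rng = np.random.default_rng(0)
        sch = lambda: lv.TreatmentSchedule(
            np.array([91.0, 140.0, 189.0, 238.0]),
            (rng.random((4, 70)) < 0.5).astype(int), sites_std.dose)
        results = {(y, b): [sch() for _ in range(10)]
                   for y in (2020, 2021, 2022) for b in (0.25, 0.5, 0.75)}
        obs = lv.build_treatment_observations(results, sites_std)
        assert len(obs) == 25200  # 70 sites x 3 years x 3 budgets x 10 sims x 4 rounds
        # all covariates standardized
        for c in ["log_vmax", "log_area", "log_dose", "mean_neighbor_dist",
                  "neighbors_within_lambda", "local_clustering"]:
            assert obs[c].mean() == pytest.approx(0.0, abs=1e-9)
            assert obs[c].std() == pytest.approx(1.0, rel=1e-3)

    def test_neighbor_count_within_dispersal_scale(self):
        sites = lv.SiteTable(["a", "b", "c"], [0.0, 100.0, 150.0], [0, 0, 0],
                             [1, 2, 3], [10, 20, 30], [10, 10, 10])
        cov = lv.site_covariates(sites, lam=110.3)
        assert cov["neighbors_within_lambda"].tolist() == [1.0, 2.0, 1.0]
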