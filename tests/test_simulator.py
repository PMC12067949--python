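"""Simulator correctness: closed-form limits, impulse exactness, positivity,
quadrature accuracy, equilibrium against an algebraic root-finder, and an
independent adaptive-solver cross-check."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

import larvopt as lv
from larvopt.environment import VitalRates, WeatherSeries


def constant_weather(tmin, tmax, rain_daily, n_days=365, year=2021):
    dates = pd.date_range(f"{year}-01-01", periods=n_days)
    return WeatherSeries(dates, np.full(n_days, tmin), np.full(n_days, tmax),
                         np.full(n_days, rain_daily))


def one_site(area=2.0, vmax=200.0, dose=10.0):
    return lv.SiteTable(["s"], [0.0], [0.0], [area], [vmax], [dose])


CONST_RATES = dict(alpha=2.0, mu=0.09, delta_L=0.04, delta_A=0.05)


def constant_rates(alpha=None, **over):
    vals = {**CONST_RATES, **over}
    if alpha is not None:
        vals["alpha"] = alpha
    return VitalRates(
        alpha=lambda T: np.full_like(np.asarray(T, float), vals["alpha"]),
        mu=lambda T: np.full_like(np.asarray(T, float), vals["mu"]),
        delta_L=lambda T: np.full_like(np.asarray(T, float), vals["delta_L"]),
        delta_A=lambda T: np.full_like(np.asarray(T, float), vals["delta_A"]),
    )


class TestClosedFormLimits:
    def test_origin_is_fixed_point(self, params, rates, weather_std, sites_small):
        traj = lv.simulate(sites_small, weather_std, rates, params)
        assert np.all(traj.L == 0) and np.all(traj.A == 0) and np.all(traj.c == 0)

    def test_larvicide_only_exponential_decay(self, params):
        # alpha = 0, L = 0: dc/dt = -kappa_c c exactly, c(t) = e^{-0.089 t}
        w = constant_weather(15, 25, 5, n_days=60)
        traj = lv.simulate(one_site(), w, constant_rates(alpha=0.0), params,
                           init={"c": np.array([1.0])})
        expect = np.exp(-params.kappa_c * traj.t)
        np.testing.assert_allclose(traj.c[:, 0], expect, rtol=1e-10)
        # 1/e time: 1/0.089 = 11.236 days
        t_e = 1.0 / params.kappa_c
        assert np.interp(t_e, traj.t, traj.c[:, 0]) == pytest.approx(np.exp(-1), rel=1e-3)

    def test_constant_forcing_equilibrium_matches_root_finder(self, params):
        # single site, constant T and R21, no control: (L, A) converge to the
        # positive steady state; cross-check with an independent 1-D root solve
        # (horizon long enough for the slow ~0.02/day eigenmode to die out)
        w = constant_weather(18, 28, 5, n_days=1100)
        sites = one_site()
        rates = constant_rates()
        a, mu, dL, dA = (CONST_RATES["alpha"], CONST_RATES["mu"],
                         CONST_RATES["delta_L"], CONST_RATES["delta_A"])
        V = float(lv.water_volume(sites.area, sites.vmax, w.r21[40], params)[0])
        K = float(lv.carrying_capacity(V, params))
        # 0 = a*A - (mu+dL)L - L^2/K with A = mu L / (2 dA)
        f = lambda L: a * mu * L / (2 * dA) - (mu + dL) * L - L**2 / K
        L_star = brentq(f, 1e-6, 10 * K)
        A_star = mu * L_star / (2 * dA)
        init = {"L": np.array([0.01 * K]), "A": np.array([1.0])}
        traj = lv.simulate(sites, w, rates, params, init=init, t0=30)
        # agreement to 4 significant figures
        assert traj.L[-1, 0] == pytest.approx(L_star, rel=5e-5)
        assert traj.A[-1, 0] == pytest.approx(A_star, rel=5e-5)


class TestImpulses:
    def test_jump_equals_dosage_exactly(self, sim_std, init_std, sites_std):
        rng = np.random.default_rng(5)
        xi = (rng.random((4, len(sites_std))) < 0.4).astype(int)
        sch = lv.TreatmentSchedule(np.array([100.0, 130.0, 160.0, 190.0]), xi,
                                   sites_std.dose)
        traj = sim_std.run(sch, init_std)
        assert len(traj.events) == 4
        for k, ev in enumerate(traj.events):
            np.testing.assert_array_equal(ev.c_post - ev.c_pre, xi[k] * sites_std.dose)

    def test_apply_impulse_adds_dose(self, sites_small):
        sch = lv.TreatmentSchedule(np.array([100.0, 130.0]),
                                   np.array([[1, 0, 1], [0, 0, 0]]),
                                   sites_small.dose)
        c = np.array([2.5, 1.0, 0.0])
        out = lv.apply_impulse(c, 0, sch)
        np.testing.assert_allclose(out, [12.5, 1.0, 30.0])
        np.testing.assert_allclose(lv.apply_impulse(out, 1, sch), out)  # xi == 0
        # repeated impulses accumulate
        np.testing.assert_allclose(lv.apply_impulse(lv.apply_impulse(c, 0, sch), 0, sch)[0],
                                   2.5 + 20.0)
        with pytest.raises(IndexError):
            lv.apply_impulse(c, 2, sch)

    def test_schedule_validation(self, params, sites_small):
        tight = lv.TreatmentSchedule(np.array([100.0, 110.0]),
                                     np.ones((2, 3), dtype=int), sites_small.dose)
        with pytest.raises(ValueError, match="spacing"):
            tight.validate(params)
        ok = lv.TreatmentSchedule(np.array([100.0, 130.0]),
                                  np.ones((2, 3), dtype=int), sites_small.dose)
        ok.validate(params)
        with pytest.raises(ValueError, match="budget"):
            ok.validate(params, budget=100.0)
        with pytest.raises(ValueError, match="season"):
            ok.validate(params, season=(120.0, 300.0))


class TestTrajectoryProperties:
    def test_nonnegativity(self, sim_std, init_std, sites_std):
        rng = np.random.default_rng(7)
        xi = (rng.random((4, len(sites_std))) < 0.5).astype(int)
        sch = lv.TreatmentSchedule(np.array([95.0, 140.0, 200.0, 260.0]), xi,
                                   sites_std.dose)
        traj = sim_std.run(sch, init_std)
        for arr in (traj.L, traj.A, traj.c):
            assert arr.min() >= -1e-9

    def test_adding_a_treatment_never_increases_J(self, sim_std, init_std, sites_std):
        rng = np.random.default_rng(11)
        xi = (rng.random((4, len(sites_std))) < 0.2).astype(int)
        times = np.array([100.0, 140.0, 180.0, 220.0])
        sch = lv.TreatmentSchedule(times, xi, sites_std.dose)
        J_base = sim_std.objective(sch, init_std)
        for _ in range(5):
            k = rng.integers(4)
            zeros = np.flatnonzero(xi[k] == 0)
            i = rng.choice(zeros)
            xi2 = xi.copy()
            xi2[k, i] = 1
            J_more = sim_std.objective(lv.TreatmentSchedule(times, xi2, sites_std.dose),
                                       init_std)
            assert J_more <= J_base * (1 + 1e-6)

    def test_grid_convergence(self, sites_std, weather_std, rates, params, init_std):
        """Halving the default step changes J by well under the precision at
        which objective values are quoted (0.1%), with and without control."""
        sch = lv.TreatmentSchedule(
            np.array([100.0, 140.0, 180.0, 220.0]),
            (np.random.default_rng(2).random((4, len(sites_std))) < 0.4).astype(int),
            sites_std.dose)
        for schedule in (None, sch):
            J = {}
            for dt in (0.05, 0.025):
                sim = lv.Simulator(sites_std, weather_std, rates, params, dt=dt)
                J[dt] = sim.objective(schedule, init_std)
            assert abs(J[0.05] - J[0.025]) / J[0.025] < 1e-3

    def test_tidy_frame_roundtrip(self, sim_std, init_std):
        traj = sim_std.run(None, init_std, t1=40)
        df = traj.to_frame()
        assert set(df.columns) == {"t", "site_id", "L", "A", "c"}
        assert len(df) == traj.t.size * traj.L.shape[1]


class TestObjective:
    def test_zero_and_constant_trajectories(self, sites_small):
        t = np.arange(0.0, 11.0)
        Z = np.zeros((11, 3))
        traj = lv.Trajectory(t, Z, Z.copy(), Z.copy(), sites_small.site_id)
        assert lv.objective_J(traj) == 0.0
        traj.A = np.full((11, 3), 2.0)  # sum A = 6 over 10 days
        assert lv.objective_J(traj) == pytest.approx(60.0)

    def test_matches_refined_quadrature_within_tolerance(self, sites_small):
        # random smooth trajectory: daily trapezoid vs 10x finer sampling
        rng = np.random.default_rng(4)
        coef = rng.normal(size=(4, 3))

        def A_of(t):
            t = np.asarray(t, float)[:, None]
            return np.abs(coef[0] + coef[1] * np.sin(2 * np.pi * t / 90)
                          + coef[2] * np.cos(2 * np.pi * t / 50) + coef[3] * t / 200) + 1.0

        t = np.arange(0.0, 201.0)
        tf = np.arange(0.0, 200.01, 0.1)
        Z = np.zeros((t.size, 3))
        J = lv.objective_J(lv.Trajectory(t, Z, A_of(t), Z, sites_small.site_id))
        Zf = np.zeros((tf.size, 3))
        J_fine = lv.objective_J(lv.Trajectory(tf, Zf, A_of(tf), Zf, sites_small.site_id))
        assert abs(J - J_fine) / J_fine < 1e-3

    def test_empty_trajectory_rejected(self, sites_small):
        z = np.zeros((1, 3))
        with pytest.raises(ValueError):
            lv.objective_J(lv.Trajectory(np.array([0.0]), z, z, z, sites_small.site_id))


class TestCrossCheck:
    def test_agrees_with_adaptive_reference_solver(self, params):
        """Dual-route check: exponential integrator vs scipy solve_ivp on a
        3-site scenario with one impulse."""
        rng = np.random.default_rng(9)
        n_days = 120
        dates = pd.date_range("2021-04-01", periods=n_days)
        tmin = 14 + 4 * np.sin(np.arange(n_days) / 20) + rng.normal(0, 1, n_days)
        tmax = tmin + 8
        rain = np.where(rng.random(n_days) < 0.3, rng.gamma(1, 8, n_days), 0.0)
        w = WeatherSeries(dates, tmin, tmax, rain)
        sites = lv.SiteTable(["a", "b", "c"], [0, 80, 160], [0, 0, 0],
                             [1.0, 2.0, 3.0], [100.0, 200.0, 300.0], [10, 10, 20])
        rates = lv.synthetic_rates()
        sch = lv.TreatmentSchedule(np.array([40.0]), np.array([[1, 0, 1]]), sites.dose)
        init = {"L": np.array([50.0, 100.0, 20.0]), "A": np.array([10.0, 5.0, 1.0])}
        sim = lv.Simulator(sites, w, rates, params, dt=0.01)
        traj = sim.run(sch, init)

        daily = rates.daily(w)
        V = lv.water_volume(sites.area[None, :], sites.vmax[None, :],
                            w.r21[:, None], params)
        K = lv.carrying_capacity(V, params)
        M = lv.dispersal_matrix(sites, params)
        rowsum = M.sum(1)

        def rhs(t, y):
            d = min(int(t), n_days - 1)
            L, A, c = y[:3], y[3:6], y[6:]
            dL = (daily["alpha"][d] * A - (daily["mu"][d] + daily["delta_L"][d]) * L
                  - L**2 / K[d] - params.tau * c * L / V[d])
            dA = 0.5 * daily["mu"][d] * L - daily["delta_A"][d] * A - (rowsum * A - M @ A)
            dc = -params.kappa_c * c - params.kappa_L * c * L / V[d]
            return np.concatenate([dL, dA, dc])

        y = np.concatenate([init["L"], init["A"], np.zeros(3)])
        sol1 = solve_ivp(rhs, (0, 40), y, rtol=1e-9, atol=1e-10, max_step=1.0)
        y2 = sol1.y[:, -1].copy()
        y2[6:] += sch.xi[0] * sites.dose
        sol2 = solve_ivp(rhs, (40, n_days - 1), y2, rtol=1e-9, atol=1e-10, max_step=1.0)
        ref = sol2.y[:, -1]
        end = np.concatenate([traj.L[-1], traj.A[-1], traj.c[-1]])
        scale = np.abs(ref) + 1e-3 * max(np.abs(ref).max(), 1.0)
        np.testing.assert_allclose(end / scale, ref / scale, atol=2e-3)
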