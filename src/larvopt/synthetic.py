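"""Synthetic weather, breeding-site layouts and allocation datasets.

The generators emulate the statistical structure of the study system — a
Mediterranean coastal garden: sinusoidal annual temperature cycles with daily
noise, episodic occurrence-amount rainfall with a mid-summer dry-down, a
70-site layout in three spatial clusters with heterogeneous, size-correlated
site geometry, and the {10, 20, 30} g dose grouping.  Defaults are calibrated
so the treatment-season (April-October) mean temperature falls near 19-21 °C
and the mean 21-day cumulative rainfall near 25-55 mm, matching the ranges of
the study years.  Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import SiteTable, WeatherSeries
from .stats import COVARIATE_NAMES, site_covariates

__all__ = [
    "SyntheticWeatherConfig",
    "SyntheticSiteConfig",
    "generate_weather",
    "generate_sites",
    "generate_allocation_dataset",
]


@dataclass
class SyntheticWeatherConfig:
    """Annual weather generator settings.

    Temperatures follow independent Tmin/Tmax sinusoids (°C) peaking at
    ``phase_doy`` plus Gaussian daily noise; rainfall is Bernoulli occurrence
    with a semiannual probability cycle (wet spring and autumn, dry mid-summer
    and winter) times a gamma-distributed amount (mm).
    """

    year: int = 2021
    tmin_mean: float = 12.0
    tmin_amp: float = 7.0
    tmax_mean: float = 20.0
    tmax_amp: float = 7.0
    phase_doy: float = 207.0        # warmest day of the year (late July)
    noise_sd: float = 1.5
    rain_prob_mean: float = 0.22
    rain_prob_amp: float = 0.10
    rain_prob_phase_doy: float = 100.0  # spring occurrence peak (semiannual cycle)
    rain_shape: float = 0.8
    rain_scale: float = 12.0
    seed: int = 0


@dataclass
class SyntheticSiteConfig:
    """Breeding-site layout generator settings.

    ``n`` sites scattered (Gaussian, sd ``cluster_spread`` m) around
    ``n_clusters`` centers at mutual distance ``cluster_distance`` m —
    mimicking interconnected garden sections.  Surface areas are log-normal;
    maximum water-holding capacity is area times a log-normal effective depth,
    which makes vmax positively correlated with area.
    """

    n: int = 70
    n_clusters: int = 3
    cluster_spread: float = 25.0
    cluster_distance: float = 150.0
    log_area_mean: float = 0.0      # ln m^2; median 1 m^2
    log_area_sd: float = 0.8
    log_depth_mean: float = -2.12   # ln m; median effective depth ~0.12 m
    log_depth_sd: float = 0.35
    seed: int = 0


def generate_weather(config: SyntheticWeatherConfig | None = None,
                     **overrides) -> WeatherSeries:
    """Generate one calendar year of daily synthetic weather."""
    cfg = config or SyntheticWeatherConfig()
    if overrides:
        cfg = SyntheticWeatherConfig(**{**cfg.__dict__, **overrides})
    rng = np.random.default_rng(cfg.seed)
    dates = pd.date_range(f"{cfg.year}-01-01", f"{cfg.year}-12-31", freq="D")
    n = len(dates)
    doy = np.arange(n, dtype=float)
    cyc = np.cos(2 * np.pi * (doy - cfg.phase_doy) / n)
    tmin = cfg.tmin_mean + cfg.tmin_amp * cyc + rng.normal(0, cfg.noise_sd, n)
    tmax = cfg.tmax_mean + cfg.tmax_amp * cyc + rng.normal(0, cfg.noise_sd, n)
    tmax = np.maximum(tmax, tmin)  # enforce the daily-range invariant
    p = cfg.rain_prob_mean + cfg.rain_prob_amp * np.cos(
        4 * np.pi * (doy - cfg.rain_prob_phase_doy) / n
    )
    p = np.clip(p, 0.0, 1.0)
    wet = rng.random(n) < p
    amounts = rng.gamma(cfg.rain_shape, cfg.rain_scale, n)
    rain = np.where(wet, amounts, 0.0)
    return WeatherSeries(dates, tmin, tmax, rain)


def _cluster_centers(k: int, dist: float) -> np.ndarray:
    """k centers at mutual distance ``dist`` (vertices of a regular polygon)."""
    if k == 1:
        return np.zeros((1, 2))
    ang = 2 * np.pi * np.arange(k) / k
    # circumradius such that adjacent vertices are `dist` apart
    r = dist / (2 * np.sin(np.pi / k))
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def generate_sites(config: SyntheticSiteConfig | None = None,
                   assign_doses: bool = True, **overrides) -> SiteTable:
    """Generate a clustered synthetic breeding-site inventory.

    When ``assign_doses`` is set, sites are stratified into the three
    {10, 20, 30} g dose groups by k-means on (area, vmax).
    """
    cfg = config or SyntheticSiteConfig()
    if overrides:
        cfg = SyntheticSiteConfig(**{**cfg.__dict__, **overrides})
    if cfg.n < 3:
        raise ValueError("need at least 3 sites")
    rng = np.random.default_rng(cfg.seed)
    centers = _cluster_centers(cfg.n_clusters, cfg.cluster_distance)
    labels = np.arange(cfg.n) % cfg.n_clusters
    xy = centers[labels] + rng.normal(0, cfg.cluster_spread, (cfg.n, 2))
    area = np.exp(rng.normal(cfg.log_area_mean, cfg.log_area_sd, cfg.n))
    depth = np.exp(rng.normal(cfg.log_depth_mean, cfg.log_depth_sd, cfg.n))
    vmax = 1000.0 * area * depth  # m^2 * m * 1000 = litres
    ids = np.array([f"s{i:03d}" for i in range(cfg.n)])
    sites = SiteTable(ids, xy[:, 0], xy[:, 1], area, vmax)
    if assign_doses:
        from .strategies import assign_dose_groups

        grouping = assign_dose_groups(sites, seed=cfg.seed)
        sites = sites.with_doses(grouping.doses)
    return sites


def generate_allocation_dataset(sites: SiteTable, true_coefficients: dict,
                                n_sims: int = 10, n_rounds: int = 4,
                                n_years: int = 3, n_budgets: int = 3,
                                intercept: float = 0.0,
                                random_intercept_sd: float = 0.9,
                                lam: float = 110.3,
                                seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Simulate treatment allocations with a known generative logistic model.

    Each (site, year, budget, simulation, round) record is drawn as
    treated ~ Bernoulli(logit^-1(intercept + X beta + u_budget)), where X are
    the standardized site covariates and u_budget are fixed draws from
    N(0, random_intercept_sd^2), one per budget level.  Returns the labeled
    table (the full default design is 70*3*3*10*4 = 25,200 records) and the
    generative truth, for parameter-recovery testing of the treatment GLMM.
    """
    unknown = set(true_coefficients) - set(COVARIATE_NAMES)
    if unknown:
        raise ValueError(f"unknown covariates in true_coefficients: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    cov = site_covariates(sites, lam)
    Z = cov[COVARIATE_NAMES].to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    beta = np.array([true_coefficients.get(c, 0.0) for c in COVARIATE_NAMES])
    u = rng.normal(0.0, random_intercept_sd, n_budgets)
    eta_site = intercept + Z @ beta

    frames = []
    for year in range(n_years):
        for b in range(n_budgets):
            for s in range(n_sims):
                for k in range(n_rounds):
                    eta = eta_site + u[b]
                    pr = 1.0 / (1.0 + np.exp(-eta))
                    df = pd.DataFrame(Z, columns=COVARIATE_NAMES)
                    df.insert(0, "site_id", cov["site_id"].to_numpy())
                    df["year"] = year
                    df["budget"] = b
                    df["sim"] = s
                    df["round"] = k
                    df["treated"] = (rng.random(len(sites)) < pr).astype(int)
                    frames.append(df)
    obs = pd.concat(frames, ignore_index=True)
    cols = ["site_id", "year", "budget", "sim", "round", "treated", *COVARIATE_NAMES]
    truth = {
        "beta": dict(zip(COVARIATE_NAMES, beta)),
        "intercept": intercept,
        "u": u,
        "random_intercept_sd": random_intercept_sd,
    }
    return obs[cols], truth
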