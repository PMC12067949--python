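"""End-to-end reproducible pipeline.

Stages: load-or-generate inputs -> dose grouping -> uncontrolled baseline J0 ->
stochastic optimization per (year, budget fraction) -> routine comparison ->
statistical post-analyses.  Every run writes a manifest with the seed
substreams and configuration needed to reproduce it byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .environment import ModelParams, SiteTable, WeatherSeries, albopictus_rates
from .io import (RunConfig, compute_cmax, read_sites_csv, read_weather_csv,
                 write_schedule_json, write_sites_csv, write_weather_csv)
from .optimizer import OptimizerConfig, optimize
from .simulator import Simulator, default_initial_conditions, objective_J
from .stats import (build_treatment_observations, climate_deviation_test,
                    delta_J, fit_dose_response, morans_i, treatment_glmm)
from .strategies import (FIRST_DAY_WINDOW, homogeneous_expectation,
                         routine_schedule, sequential_traj_provider)
from .synthetic import (SyntheticSiteConfig, SyntheticWeatherConfig,
                        generate_sites, generate_weather)

logger = logging.getLogger("larvopt")

SUBSTREAMS = ("weather", "init", "optimizer", "permutations", "routine")


class StageError(RuntimeError):
    """Pipeline failure tagged with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage {stage}] {cause}")
        self.stage = stage
        self.cause = cause


def _substream_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(SUBSTREAMS))
    return {name: ss for name, ss in zip(SUBSTREAMS, children)}


def run_pipeline(config: RunConfig, rates=None) -> dict:
    """Execute the full pipeline and return the report bundle (also on disk)."""
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    streams = _substream_seeds(config.seed)
    params = ModelParams(**config.params)
    rates = rates or albopictus_rates()
    report: dict = {"seed": config.seed, "version": __version__}

    def stage(name):
        logger.info("stage %s", name)

        class _Ctx:
            def __enter__(self):
                self.t0 = time.time()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                logger.info("stage %s done in %.1fs", name, time.time() - self.t0)

        return _Ctx()

    # ------------------------------------------------ inputs
    with stage("inputs"):
        if config.sites:
            sites = read_sites_csv(config.sites)
        else:
            sites = generate_sites(SyntheticSiteConfig(
                seed=int(np.random.default_rng(streams["weather"]).integers(2**31))
            ))
        if sites.dose is None:
            from .strategies import assign_dose_groups
            sites = sites.with_doses(assign_dose_groups(sites, seed=config.seed).doses)
        weather_by_year: dict[int, WeatherSeries] = {}
        wrng = np.random.default_rng(streams["weather"])
        if config.weather:
            w = read_weather_csv(config.weather)
            weather_by_year[w.dates[0].year] = w
        else:
            for year in config.years:
                weather_by_year[year] = generate_weather(
                    SyntheticWeatherConfig(year=year, seed=int(wrng.integers(2**31)))
                )
        write_sites_csv(sites, outdir / "sites.csv")
        for year, w in weather_by_year.items():
            write_weather_csv(w, outdir / f"weather_{year}.csv")

    cmax = compute_cmax(sites, config.n_rounds)
    report["cmax_g"] = cmax

    # ------------------------------------------------ baseline + optimization
    init_rng = np.random.default_rng(streams["init"])
    opt_rng = np.random.default_rng(streams["optimizer"])
    rout_rng = np.random.default_rng(streams["routine"])
    rows = []
    kept: dict = {}
    with stage("optimize"):
        for year, weather in weather_by_year.items():
            sim = Simulator(sites, weather, rates, params)
            init = default_initial_conditions(sites, weather, params, init_rng)
            J0 = sim.objective(None, init)
            lo, _ = sim.season()
            for frac in config.budget_fractions:
                budget = frac * cmax
                ocfg = OptimizerConfig(budget=budget,
                                       seed=int(opt_rng.integers(2**31)),
                                       **config.optimizer)
                result = optimize(sites, weather, rates, params, ocfg, init=init)
                J_opt = sim.objective(result.best_schedule, init)
                first_day = lo + rout_rng.uniform(0, FIRST_DAY_WINDOW)
                rout = routine_schedule(sites, budget, first_day,
                                        sequential_traj_provider(sim, init), params,
                                        season_start=lo)
                J_rout = sim.objective(rout, init)
                kept[(year, frac)] = result.schedules
                rows.append({
                    "year": year, "budget_fraction": frac, "budget_g": budget,
                    "J0": J0, "J_opt": J_opt, "J_rout": J_rout,
                    "dJ_opt": delta_J(J_opt, J0), "dJ_rout": delta_J(J_rout, J0),
                    "n_evaluations": result.n_evaluations,
                })
                write_schedule_json(result.best_schedule,
                                    outdir / f"schedule_opt_{year}_{frac:.2f}.json",
                                    sites.site_id)
    comparison = pd.DataFrame(rows)
    comparison.to_csv(outdir / "strategy_comparison.csv", index=False)
    report["comparison"] = comparison.to_dict(orient="records")

    # ------------------------------------------------ analyses
    with stage("analyze"):
        perm_seed = int(np.random.default_rng(streams["permutations"]).integers(2**31))
        by_frac = comparison.groupby("budget_fraction")[["dJ_opt", "dJ_rout"]].mean()
        fits = {}
        for col, label in (("dJ_opt", "optimized"), ("dJ_rout", "routine_avg")):
            fit = fit_dose_response(by_frac.index.to_numpy(), by_frac[col].to_numpy())
            fits[label] = {"linear_r2": fit.linear_r2, "exp_r2": fit.exp_r2,
                           "better": fit.better_model, "delta_aic": fit.delta_aic}
        report["dose_response"] = fits

        climate = {}
        for (year, frac), schedules in kept.items():
            times = np.concatenate([s.times for s in schedules])
            w = weather_by_year[year]
            for var in ("temperature", "r21"):
                rep = climate_deviation_test(times, w, var, params)
                climate[f"{year}_{frac:.2f}_{var}"] = rep.pvalue
        report["climate_deviation_p"] = climate

        sub_cmax = {k: v for k, v in kept.items() if k[1] < 1.0} or kept
        obs = build_treatment_observations(sub_cmax, sites, params=params)
        obs.to_csv(outdir / "treatment_observations.csv", index=False)
        report["n_observations"] = int(len(obs))
        try:
            glmm = treatment_glmm(obs)
            glmm.table.to_csv(outdir / "glmm_coefficients.csv", index=False)
            report["glmm"] = {
                "retained": glmm.retained,
                "accuracy": glmm.accuracy,
                "random_intercept_var": glmm.random_intercept_var,
            }
        except ValueError as e:
            report["glmm"] = {"error": str(e)}

        treat_prob = obs.groupby("site_id", sort=False)["treated"].mean().to_numpy()
        if treat_prob.min() < treat_prob.max():
            mi = morans_i(treat_prob, sites, seed=perm_seed)
            report["morans_i"] = {"I": mi.I, "expected": mi.expected, "p": mi.pvalue}
        dev = homogeneous_expectation([s for v in sub_cmax.values() for s in v], sites)
        pd.DataFrame({"site_id": sites.site_id, "deviation_pct": dev}).to_csv(
            outdir / "homogeneous_deviation.csv", index=False)

    # ------------------------------------------------ manifest
    manifest = {
        "config": config.to_dict(),
        "seed_substreams": {k: int(np.random.default_rng(v).integers(2**31))
                            for k, v in _substream_seeds(config.seed).items()},
        "version": __version__,
        "elapsed_s": time.time() - t_start,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
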