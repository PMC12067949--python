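"""File formats, run configuration and budget accounting.

Weather CSV: ``date, tmin_c, tmax_c, rain_mm`` (ISO-8601 dates).
Sites CSV: ``site_id, x_m, y_m, area_m2, vmax_l[, dose_g]``.
Schedules: JSON with global times, per-site 0/1 allocations and doses.
Run configuration: a single YAML/JSON file with documented defaults;
unknown keys are rejected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from .environment import SiteTable, WeatherSeries
from .simulator import TreatmentSchedule, Trajectory

__all__ = [
    "read_weather_csv", "write_weather_csv",
    "read_sites_csv", "write_sites_csv",
    "read_schedule_json", "write_schedule_json",
    "write_trajectory_csv",
    "RunConfig", "compute_cmax",
]


def read_weather_csv(path) -> WeatherSeries:
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "tmin_c", "tmax_c", "rain_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weather CSV missing columns: {sorted(missing)}")
    return WeatherSeries(df["date"], df["tmin_c"], df["tmax_c"], df["rain_mm"])


def write_weather_csv(weather: WeatherSeries, path) -> None:
    df = weather.to_frame().drop(columns="r21_mm")  # derived, not stored
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df.to_csv(path, index=False)


def read_sites_csv(path) -> SiteTable:
    df = pd.read_csv(path)
    required = {"site_id", "x_m", "y_m", "area_m2", "vmax_l"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sites CSV missing columns: {sorted(missing)}")
    return SiteTable.from_frame(df)


def write_sites_csv(sites: SiteTable, path) -> None:
    sites.to_frame().to_csv(path, index=False)


def write_schedule_json(schedule: TreatmentSchedule, path, site_ids=None) -> None:
    Path(path).write_text(json.dumps(schedule.to_dict(site_ids), indent=2))


def read_schedule_json(path, site_ids=None) -> TreatmentSchedule:
    return TreatmentSchedule.from_dict(json.loads(Path(path).read_text()), site_ids)


def write_trajectory_csv(traj: Trajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def compute_cmax(sites: SiteTable, n_rounds: int = 4) -> float:
    """Maximal seasonal budget: the amount treating every site at every round.

    C_max = n_rounds * sum_i gamma^i (g).
    """
    return float(n_rounds * sites.require_doses().sum())


@dataclass
class RunConfig:
    """Full pipeline configuration with documented defaults.

    ``weather``/``sites`` are CSV paths, or null to use the synthetic
    generators.  ``params`` and ``optimizer`` hold keyword overrides of
    :class:`~larvopt.environment.ModelParams` and
    :class:`~larvopt.optimizer.OptimizerConfig`.  All randomness flows from
    ``seed`` through named substreams (weather, init, optimizer, permutations).
    """

    weather: str | None = None
    sites: str | None = None
    params: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)
    budget_fractions: tuple = (0.25, 0.50, 0.75, 1.0)
    years: tuple = (2020, 2021, 2022)
    n_rounds: int = 4
    seed: int = 0
    outdir: str = "larvopt_run"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.budget_fractions = tuple(cfg.budget_fractions)
        cfg.years = tuple(cfg.years)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["budget_fractions"] = list(self.budget_fractions)
        d["years"] = list(self.years)
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
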