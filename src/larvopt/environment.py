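"""Model parameters and environmental forcing for the breeding-site metapopulation.

This module holds everything that turns raw inputs (daily weather, a breeding-site
inventory) into the quantities the simulator consumes:

* temperature-dependent vital rates of *Aedes albopictus* (birth, development and
  death rates, each a pluggable function of temperature);
* the rainfall-driven water volume and larval carrying capacity of each site;
* the distance-dependent adult dispersal matrix built on a Weibull kernel.

Conventions: temperatures in degrees Celsius, rainfall in mm, distances in metres,
volumes in litres, rates in day**-1.  Development- and reproduction-related rates are
evaluated at the daily *maximum* temperature, death-related rates at the daily
*minimum* — the ends of the daily range where each group of rates varies most.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "WeatherSeries",
    "SiteTable",
    "ModelParams",
    "VitalRates",
    "albopictus_rates",
    "synthetic_rates",
    "water_volume",
    "carrying_capacity",
    "dispersal_matrix",
]

R21_WINDOW = 21  # days of trailing cumulative rainfall driving water availability


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

class WeatherSeries:
    """Daily weather forcing: Tmin, Tmax, rainfall, and derived 21-day rainfall.

    Parameters
    ----------
    dates : sequence of datetime-like
        Contiguous, strictly increasing calendar days.
    tmin, tmax : array-like, °C
        Daily minimum / maximum temperature; ``tmax >= tmin`` everywhere.
    rain : array-like, mm
        Daily rainfall, nonnegative.

    The cumulative rainfall ``r21`` (trailing 21-day sum, including the current
    day, shorter at the start of the series) is derived on construction.
    """

    def __init__(self, dates, tmin, tmax, rain):
        dates = pd.DatetimeIndex(dates)
        tmin = np.asarray(tmin, dtype=float)
        tmax = np.asarray(tmax, dtype=float)
        rain = np.asarray(rain, dtype=float)
        n = len(dates)
        if not (len(tmin) == len(tmax) == len(rain) == n):
            raise ValueError("dates, tmin, tmax and rain must have equal length")
        if n == 0:
            raise ValueError("empty weather series")
        deltas = np.diff(dates.values).astype("timedelta64[D]").astype(int)
        if n > 1 and not np.all(deltas == 1):
            raise ValueError("dates must be strictly increasing daily with no gaps")
        if np.any(tmax < tmin):
            raise ValueError("tmax must be >= tmin on every day")
        if np.any(rain < 0):
            raise ValueError("rainfall must be nonnegative")
        if np.any(~np.isfinite(tmin)) or np.any(~np.isfinite(tmax)) or np.any(~np.isfinite(rain)):
            raise ValueError("weather values must be finite")
        self.dates = dates
        self.tmin = tmin
        self.tmax = tmax
        self.rain = rain
        self.r21 = (
            pd.Series(rain).rolling(R21_WINDOW, min_periods=1).sum().to_numpy()
        )

    def __len__(self) -> int:
        return len(self.dates)

    @property
    def tmid(self) -> np.ndarray:
        """Daily temperature midpoint (Tmin + Tmax) / 2, °C."""
        return 0.5 * (self.tmin + self.tmax)

    def day_index(self, when) -> int:
        """Offset (in days) of a calendar date within the series."""
        ts = pd.Timestamp(when)
        off = (ts - self.dates[0]).days
        if not 0 <= off < len(self):
            raise KeyError(f"{ts.date()} outside weather series")
        return off

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates,
                "tmin_c": self.tmin,
                "tmax_c": self.tmax,
                "rain_mm": self.rain,
                "r21_mm": self.r21,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "WeatherSeries":
        return cls(df["date"], df["tmin_c"], df["tmax_c"], df["rain_mm"])


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

class SiteTable:
    """Breeding-site inventory: planar coordinates, geometry and treatment dose.

    Each site is a water-holding container (typically a storm or sewage drain)
    characterized by its position (x, y in metres), surface area (m²), maximum
    water-holding capacity ``vmax`` (L) and, once assigned, the fixed larvicide
    dose (g per application, one of 10/20/30).
    """

    DOSES = (10.0, 20.0, 30.0)

    def __init__(self, site_id, x, y, area, vmax, dose=None):
        self.site_id = np.asarray(site_id)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.area = np.asarray(area, dtype=float)
        self.vmax = np.asarray(vmax, dtype=float)
        n = self.site_id.size
        if len(set(map(str, self.site_id))) != n:
            raise ValueError("site_id labels must be unique")
        for name, arr in (("x", self.x), ("y", self.y), ("area", self.area), ("vmax", self.vmax)):
            if arr.size != n:
                raise ValueError(f"{name} length mismatch")
        if np.any(self.area <= 0) or np.any(self.vmax <= 0):
            raise ValueError("area and vmax must be strictly positive")
        if dose is None:
            self.dose = None
        else:
            self.dose = np.asarray(dose, dtype=float)
            if self.dose.size != n:
                raise ValueError("dose length mismatch")
            if np.any(self.dose <= 0):
                raise ValueError("doses must be positive")

    def __len__(self) -> int:
        return self.site_id.size

    @property
    def n_sites(self) -> int:
        return len(self)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def distances(self) -> np.ndarray:
        """Pairwise planar Euclidean distance matrix (m), zero diagonal."""
        if len(self) == 1:
            return np.zeros((1, 1))
        return squareform(pdist(self.coords))

    def require_doses(self) -> np.ndarray:
        if self.dose is None:
            raise ValueError("sites have no assigned doses; run assign_dose_groups first")
        return self.dose

    def with_doses(self, dose) -> "SiteTable":
        return SiteTable(self.site_id, self.x, self.y, self.area, self.vmax, dose)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "site_id": self.site_id,
                "x_m": self.x,
                "y_m": self.y,
                "area_m2": self.area,
                "vmax_l": self.vmax,
            }
        )
        if self.dose is not None:
            df["dose_g"] = self.dose
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SiteTable":
        dose = df["dose_g"] if "dose_g" in df.columns else None
        return cls(df["site_id"], df["x_m"], df["y_m"], df["area_m2"], df["vmax_l"], dose)


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Model constants.

    Defaults are the study values: larvicide decay/removal/toxicity fitted from
    residual-activity bioassays, dispersal kernel shape/scale from mark-release
    experiments, water retention and larvae-per-litre proportionality constants.

    Attributes
    ----------
    kappa_c : float
        Intrinsic larvicide decay rate, day**-1.
    kappa_L : float
        Active larvicide removal (ingestion) rate, L larva**-1 day**-1.
    tau : float
        Larvicide toxicity, L g**-1 day**-1.
    nu_R : float
        Breeding-site water retention (fraction of rainfall retained).
    nu_K : float
        Water-to-larvae proportionality, larvae L**-1.
    sigma : float
        Dispersal strength, m day**-1.
    s, lam : float
        Weibull kernel shape (dimensionless, must exceed 1) and scale (m).
    v_floor : float
        Numerical floor on water volume (L): the larval and larvicide loss terms
        divide by V, so a strictly dry site is replaced by residual moisture.
    t_min_spacing : float
        Minimal time between two treatments, days.
    season : (str, str)
        Treatment-season window as "MM-DD" strings, inclusive.
    """

    kappa_c: float = 0.089
    kappa_L: float = 0.021
    tau: float = 407.66
    nu_R: float = 0.75
    nu_K: float = 106.7
    sigma: float = 12.59
    s: float = 1.323
    lam: float = 110.3
    v_floor: float = 0.1
    t_min_spacing: float = 21.0
    season: tuple = ("04-01", "10-31")

    def __post_init__(self):
        for name in ("kappa_c", "kappa_L", "tau", "nu_R", "nu_K", "sigma", "lam", "v_floor", "t_min_spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.s <= 1:
            raise ValueError("Weibull shape s must exceed 1 (kernel diverges at d=0 otherwise)")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def season_days(self, weather: WeatherSeries) -> tuple[int, int]:
        """Season window as (start, end) day offsets into a weather series."""
        year = weather.dates[0].year
        start = weather.day_index(f"{year}-{self.season[0]}")
        end = weather.day_index(f"{year}-{self.season[1]}")
        return start, end


# ---------------------------------------------------------------------------
# Vital rates
# ---------------------------------------------------------------------------

RateFn = Callable[[np.ndarray], np.ndarray]


@dataclass
class VitalRates:
    """Pluggable temperature responses of the mosquito life cycle.

    ``alpha`` (larval birth rate per adult) and ``mu`` (larva-to-adult
    development rate) are evaluated at the daily maximum temperature; the death
    rates ``delta_L`` and ``delta_A`` at the daily minimum.  All four must be
    nonnegative for any finite temperature.
    """

    alpha: RateFn
    mu: RateFn
    delta_L: RateFn
    delta_A: RateFn

    def daily(self, weather: WeatherSeries) -> dict[str, np.ndarray]:
        """Evaluate all rates on a weather series (fixed Tmax/Tmin convention)."""
        out = {
            "alpha": np.asarray(self.alpha(weather.tmax), dtype=float),
            "mu": np.asarray(self.mu(weather.tmax), dtype=float),
            "delta_L": np.asarray(self.delta_L(weather.tmin), dtype=float),
            "delta_A": np.asarray(self.delta_A(weather.tmin), dtype=float),
        }
        for name, arr in out.items():
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise ValueError(f"vital rate {name} returned negative or non-finite values")
        return out


def _briere(T, q, T0, Tm):
    T = np.asarray(T, dtype=float)
    out = q * T * (T - T0) * np.sqrt(np.clip(Tm - T, 0.0, None))
    return np.clip(np.where((T > T0) & (T < Tm), out, 0.0), 0.0, None)


def albopictus_rates() -> VitalRates:
    """Default *Ae. albopictus* thermal responses.

    Smooth parameterizations of the published thermal-performance literature for
    this species: Brière curves (q·T·(T−T0)·√(Tm−T), zero outside (T0, Tm)) for
    the hump-shaped birth and development rates, with optima near 31–33 °C, and
    saturating U-shaped quadratics for the larval and adult death rates with
    minima near 25 °C and 23 °C.  Magnitudes at the optimum: birth ≈ 8 larvae
    adult⁻¹ day⁻¹ (tens of eggs per gonotrophic cycle times hatch success),
    development ≈ 0.10 day⁻¹, larval death ≈ 0.02 day⁻¹, adult death
    ≈ 0.03 day⁻¹; death rates cap at 0.15 and 0.08 day⁻¹ at the thermal
    extremes (mortality saturates rather than diverges — the model carries no
    diapausing egg stage, so winter survival of the modeled stages has to
    stand in for the egg bank that reseeds the population in spring).  These
    are a documented default, not a fit to any particular dataset; replace
    with measured curves where available.
    """
    return VitalRates(
        alpha=lambda T: _briere(T, 4.5e-3, 10.25, 38.8),
        mu=lambda T: _briere(T, 5.1e-5, 10.3, 41.0),
        delta_L=lambda T: np.minimum(
            0.0235 + 8.8e-4 * (np.asarray(T, float) - 25.3) ** 2, 0.15
        ),
        delta_A=lambda T: np.minimum(
            0.027 + 6.9e-4 * (np.asarray(T, float) - 22.6) ** 2, 0.08
        ),
    )


def synthetic_rates() -> VitalRates:
    """Simple smooth rate family used throughout the test-suite.

    Gaussian bumps for birth/development (peaks at 28.5 °C and 28 °C, width
    9 °C) and saturating U-shaped death rates (caps 0.15 / 0.08 day⁻¹);
    everywhere positive and finite.  Calibrated so the seasonal cycle under
    the default synthetic weather reproduces the qualitative study dynamics:
    winter collapse, rapid late-spring growth, and a rainfall-modulated
    summer plateau near carrying capacity.
    """
    return VitalRates(
        alpha=lambda T: 8.0 * np.exp(-(((np.asarray(T, float) - 28.5) / 9.0) ** 2)),
        mu=lambda T: 0.11 * np.exp(-(((np.asarray(T, float) - 28.0) / 9.0) ** 2)),
        delta_L=lambda T: np.minimum(
            0.02 + 1.0e-3 * (np.asarray(T, float) - 26.0) ** 2, 0.15
        ),
        delta_A=lambda T: np.minimum(
            0.03 + 8.0e-4 * (np.asarray(T, float) - 23.0) ** 2, 0.08
        ),
    )


# ---------------------------------------------------------------------------
# Water volume, carrying capacity, dispersal
# ---------------------------------------------------------------------------

def water_volume(area, vmax, r21, params: ModelParams):
    """Water volume (L) held by a site under trailing 21-day rainfall ``r21``.

    V = max(min(nu_R * r21 * area, vmax), v_floor): proportional to surface
    area and cumulative rainfall (mm * m² = L), saturating at the site's
    maximum water-holding capacity, floored at residual moisture ``v_floor``.
    Monotone nondecreasing in r21.
    """
    area = np.asarray(area, dtype=float)
    r21 = np.asarray(r21, dtype=float)
    if np.any(r21 < 0):
        raise ValueError("r21 must be nonnegative")
    if np.any(area <= 0):
        raise ValueError("area must be strictly positive")
    v = np.minimum(params.nu_R * r21 * area, vmax)
    return np.maximum(v, params.v_floor)


def carrying_capacity(volume, params: ModelParams):
    """Larval carrying capacity K = nu_K * V (larvae), linear in water volume."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume < 0):
        raise ValueError("volume must be nonnegative")
    return params.nu_K * volume


def weibull_kernel(d, params: ModelParams):
    """Dispersal rate (day**-1) at distance d (m).

    m(d) = sigma * (s/lam) * (d/lam)**(s-1) * exp(-(d/lam)**s) — the Weibull
    density scaled by the dispersal strength sigma.  Because s > 1 the kernel
    vanishes at d = 0 and has a unique interior maximum at
    d* = lam * ((s-1)/s)**(1/s).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    z = d / params.lam
    with np.errstate(divide="ignore", invalid="ignore"):
        out = params.sigma * (params.s / params.lam) * z ** (params.s - 1.0) * np.exp(-(z ** params.s))
    return np.where(d == 0.0, 0.0, out)


def dispersal_matrix(sites: SiteTable, params: ModelParams) -> np.ndarray:
    """N×N adult dispersal-rate matrix m_ij (day**-1).

    Symmetric, zero diagonal, nonnegative.  Coincident distinct sites get rate 0
    (the kernel vanishes at zero distance for s > 1).
    """
    if len(sites) < 1:
        raise ValueError("at least one site required")
    m = weibull_kernel(sites.distances(), params)
    np.fill_diagonal(m, 0.0)
    return m
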