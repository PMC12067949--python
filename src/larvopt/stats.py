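"""Post-hoc analyses of optimized treatment strategies.

Covers the strategy-comparison statistics: percentage population reduction
(delta_J), linear-vs-exponential dose-response fits with AIC model comparison,
climate-deviation tests at treatment times, the treatment-probability mixed
logistic regression with AICc backward selection, global spatial
autocorrelation (Moran's I) and the weighted local clustering covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import mannwhitneyu, wilcoxon

from ._glmm import GLMMFit, SeparationError, fit_mixed_logit
from .environment import ModelParams, SiteTable, WeatherSeries

__all__ = [
    "delta_J",
    "DoseResponseFit",
    "fit_dose_response",
    "ClimateDeviationReport",
    "climate_deviation_test",
    "build_treatment_observations",
    "site_covariates",
    "GLMMReport",
    "treatment_glmm",
    "MoransIResult",
    "morans_i",
    "local_clustering",
    "SeparationError",
]

COVARIATE_NAMES = [
    "log_vmax",
    "log_area",
    "log_dose",
    "mean_neighbor_dist",
    "neighbors_within_lambda",
    "local_clustering",
]


# ---------------------------------------------------------------------------
# Cost-effectiveness
# ---------------------------------------------------------------------------

def delta_J(J_strategy: float, J_uncontrolled: float) -> float:
    """Percentage change of the objective versus no control.

    100 * (J - J0) / J0: 0 when the strategy achieves nothing, -100 at
    eradication.  Scale-invariant in (J, J0).
    """
    if J_uncontrolled <= 0:
        raise ValueError("uncontrolled objective J0 must be positive")
    return 100.0 * (J_strategy - J_uncontrolled) / J_uncontrolled


@dataclass
class DoseResponseFit:
    """Linear and saturating-exponential fits to (budget fraction, delta-J) points."""

    c: np.ndarray
    dJ: np.ndarray
    linear_coef: tuple          # (slope, intercept)
    linear_r2: float
    linear_aic: float
    exp_coef: tuple             # (a, b) of dJ = a (1 - exp(-b c))
    exp_r2: float
    exp_aic: float

    @property
    def better_model(self) -> str:
        return "linear" if self.linear_aic < self.exp_aic else "exponential"

    @property
    def delta_aic(self) -> float:
        """AIC(worse model) - AIC(better model), >= 0."""
        return float(abs(self.linear_aic - self.exp_aic))


def _gaussian_aic(ss_res: float, n: int, k_mean_params: int) -> float:
    # AIC from the Gaussian log-likelihood with sigma^2 = SSres / n profiled
    # out; k counts the mean parameters plus sigma.
    k = k_mean_params + 1
    if ss_res <= 0:
        ss_res = np.finfo(float).tiny
    return n * (np.log(2 * np.pi * ss_res / n) + 1) + 2 * k


def fit_dose_response(c, dJ, anchor_origin: bool = True) -> DoseResponseFit:
    """Fit delta-J as a function of the budget fraction c in [0, 1].

    Ordinary least squares line and the saturating exponential
    dJ = a (1 - exp(-b c)) (nonlinear least squares); the origin (0, 0) — no
    larvicide, no reduction — is included as an anchor point unless already
    present.  Reports R^2 and Gaussian AIC for both models on the identical
    point set.
    """
    c = np.asarray(c, dtype=float)
    dJ = np.asarray(dJ, dtype=float)
    if anchor_origin and not np.any((c == 0) & (dJ == 0)):
        c = np.concatenate([[0.0], c])
        dJ = np.concatenate([[0.0], dJ])
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct budget fractions to fit")
    n = c.size
    ss_tot = float(np.sum((dJ - dJ.mean()) ** 2))

    A = np.column_stack([c, np.ones(n)])
    coef, *_ = np.linalg.lstsq(A, dJ, rcond=None)
    ss_lin = float(np.sum((dJ - A @ coef) ** 2))
    r2_lin = 1.0 - ss_lin / ss_tot
    aic_lin = _gaussian_aic(ss_lin, n, 2)

    def f(x, a, b):
        return a * (1.0 - np.exp(-b * x))

    p0 = (min(dJ.min(), -1.0), 3.0)
    popt, _ = curve_fit(f, c, dJ, p0=p0, maxfev=20000)
    ss_exp = float(np.sum((dJ - f(c, *popt)) ** 2))
    r2_exp = 1.0 - ss_exp / ss_tot
    aic_exp = _gaussian_aic(ss_exp, n, 2)

    return DoseResponseFit(
        c=c, dJ=dJ,
        linear_coef=(float(coef[0]), float(coef[1])), linear_r2=r2_lin, linear_aic=aic_lin,
        exp_coef=(float(popt[0]), float(popt[1])), exp_r2=r2_exp, exp_aic=aic_exp,
    )


# ---------------------------------------------------------------------------
# Climate deviations at treatment times
# ---------------------------------------------------------------------------

@dataclass
class ClimateDeviationReport:
    variable: str
    statistic: float
    pvalue: float
    deviations: np.ndarray          # % deviation at each treatment time
    background: np.ndarray          # % deviation on every season day
    treatment_days: np.ndarray      # day offsets of treatments in the series
    early: np.ndarray               # deviations at times on/before the mid-season split
    late: np.ndarray
    method: str


def climate_deviation_test(treatment_times, weather: WeatherSeries, variable: str,
                           params: ModelParams | None = None,
                           method: str = "wilcoxon", n_perm: int = 9999,
                           seed: int | None = 0,
                           mid_season: str = "07-15") -> ClimateDeviationReport:
    """Test whether climate at treatment times deviates from the season norm.

    The daily scalar is the Tmin/Tmax midpoint for ``variable="temperature"``
    or the 21-day cumulative rainfall for ``variable="r21"``; deviations are
    percentages of the season mean (season window from ``params``, 1 April to
    31 October by default).

    ``method``:
      * "wilcoxon" (default) — one-sample signed-rank of the treatment-time
        deviations against the season *median* deviation (a sample of all-zero
        differences yields p = 1, reported without a statistic);
      * "mannwhitney" — two-sample rank test against the background days;
      * "permutation" — seeded Monte-Carlo test of the mean treatment-time
        deviation against means of same-sized random draws of season days.

    The report also carries the before/after mid-season (15 July) split of the
    deviations.  Note that percentage deviations are *not* invariant to adding
    a constant to the underlying variable (the season mean changes); absolute
    deviations in native units would be.
    """
    params = params or ModelParams()
    if variable == "temperature":
        series = weather.tmid
    elif variable == "r21":
        series = weather.r21
    else:
        raise ValueError("variable must be 'temperature' or 'r21'")
    lo, hi = params.season_days(weather)
    season_vals = series[lo:hi + 1]
    mean = season_vals.mean()
    if mean == 0:
        raise ValueError("season mean is zero: percentage deviations undefined")
    background = 100.0 * (season_vals - mean) / mean

    days = np.floor(np.asarray(treatment_times, dtype=float)).astype(int)
    if np.any(days < lo) or np.any(days > hi):
        raise ValueError("treatment times outside the season window")
    if days.size < 1:
        raise ValueError("at least one treatment time required")
    dev = background[days - lo]

    if method == "wilcoxon":
        diffs = dev - np.median(background)
        if np.allclose(diffs, 0.0):
            stat, p = np.nan, 1.0
        else:
            stat, p = wilcoxon(diffs)
    elif method == "mannwhitney":
        stat, p = mannwhitneyu(dev, background)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        obs = dev.mean()
        draws = rng.choice(background, size=(n_perm, dev.size), replace=True).mean(axis=1)
        p = (1 + np.sum(np.abs(draws - background.mean()) >= abs(obs - background.mean()))) / (n_perm + 1)
        stat = obs
    else:
        raise ValueError(f"unknown method {method!r}")

    year = weather.dates[0].year
    split = weather.day_index(f"{year}-{mid_season}")
    return ClimateDeviationReport(
        variable=variable, statistic=float(stat), pvalue=float(p),
        deviations=dev, background=background, treatment_days=days,
        early=dev[days <= split], late=dev[days > split], method=method,
    )


# ---------------------------------------------------------------------------
# Spatial covariates
# ---------------------------------------------------------------------------

def local_clustering(sites: SiteTable) -> np.ndarray:
    """Weighted local clustering coefficient of each site, in [0, 1].

    Computed on the fully connected graph with edge weights 1/d(i, j) using
    the geometric-mean (intensity) formulation with weights normalized by the
    maximum edge weight.
    """
    if len(sites) < 3:
        raise ValueError("need at least 3 sites")
    d = sites.distances()
    off = ~np.eye(len(sites), dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("duplicate coordinates produce infinite edge weights")
    G = nx.Graph()
    ids = list(range(len(sites)))
    for i in ids:
        for j in ids[i + 1:]:
            G.add_edge(i, j, weight=1.0 / d[i, j])
    cc = nx.clustering(G, weight="weight")
    return np.array([cc[i] for i in ids])


def site_covariates(sites: SiteTable, lam: float) -> pd.DataFrame:
    """Per-site covariates of the treatment-probability analysis (unstandardized).

    Natural-log transforms of vmax, area and dose; mean distance to the other
    sites; number of sites strictly within the dispersal scale ``lam``; and the
    weighted local clustering coefficient.
    """
    doses = sites.require_doses()
    d = sites.distances()
    off = ~np.eye(len(sites), dtype=bool)
    mean_dist = np.array([d[i][off[i]].mean() for i in range(len(sites))])
    n_within = np.array([(d[i][off[i]] < lam).sum() for i in range(len(sites))])
    return pd.DataFrame(
        {
            "site_id": sites.site_id,
            "log_vmax": np.log(sites.vmax),
            "log_area": np.log(sites.area),
            "log_dose": np.log(doses),
            "mean_neighbor_dist": mean_dist,
            "neighbors_within_lambda": n_within.astype(float),
            "local_clustering": local_clustering(sites),
        }
    )


def build_treatment_observations(results: dict, sites: SiteTable,
                                 lam: float | None = None,
                                 params: ModelParams | None = None) -> pd.DataFrame:
    """Flatten kept schedules into one binary record per site-round-simulation.

    Parameters
    ----------
    results : dict
        Maps (year, budget_label) to a list of schedules (the kept
        best-performing simulations for that year and budget level).
    sites : SiteTable
        Covariates are computed once per site and standardized across the
        final table.
    lam : float
        Neighborhood radius for the neighbor count (defaults to the dispersal
        scale in ``params``).

    Returns a DataFrame with columns (site_id, year, budget, sim, round,
    treated, <standardized covariates>).
    """
    if not results:
        raise ValueError("results must be nonempty")
    params = params or ModelParams()
    lam = params.lam if lam is None else lam
    cov = site_covariates(sites, lam)
    rows = []
    for (year, budget), schedules in results.items():
        for sim_id, sch in enumerate(schedules):
            for k in range(sch.n_rounds):
                df = cov.copy()
                df["year"] = year
                df["budget"] = budget
                df["sim"] = sim_id
                df["round"] = k
                df["treated"] = np.asarray(sch.xi[k], dtype=int)
                rows.append(df)
    obs = pd.concat(rows, ignore_index=True)
    for name in COVARIATE_NAMES:
        v = obs[name].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            raise ValueError(f"covariate {name} is constant; cannot standardize")
        obs[name] = (v - v.mean()) / sd
    cols = ["site_id", "year", "budget", "sim", "round", "treated", *COVARIATE_NAMES]
    return obs[cols]


# ---------------------------------------------------------------------------
# Treatment-probability GLMM
# ---------------------------------------------------------------------------

@dataclass
class GLMMReport:
    """Backward-selected mixed-logistic model of treatment probability."""

    fit: GLMMFit
    table: pd.DataFrame             # coefficient table of the final model
    retained: list                  # covariate names kept by AICc deletion
    random_intercept_var: float
    aicc_path: list                 # (description, AICc) after each deletion step
    accuracy: float                 # correct-classification rate at threshold 0.5
    confusion: np.ndarray           # 2x2 [true 0/1 x predicted 0/1]
    n_obs: int


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column of a standardized design."""
    p = X.shape[1]
    out = np.empty(p)
    for j in range(p):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([others, np.ones(X.shape[0])])
        coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ coef
        ss_tot = np.sum((X[:, j] - X[:, j].mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def treatment_glmm(obs: pd.DataFrame, covariates: list | None = None,
                   group_col: str = "budget", response_col: str = "treated",
                   vif_threshold: float = 10.0) -> GLMMReport:
    """Mixed logistic regression treated ~ covariates + (1 | budget).

    Backward deletion: starting from the full covariate set, repeatedly drop
    the single covariate whose removal most improves (lowers) the
    small-sample-corrected AICc, preferring high-collinearity covariates
    (VIF above ``vif_threshold``) as deletion candidates while any remain;
    stop when no deletion improves.  Reports the final coefficient table,
    the random-intercept variance across budget levels, the AICc path, and
    classification accuracy at the 0.5 threshold.
    """
    covariates = list(covariates) if covariates is not None else list(COVARIATE_NAMES)
    y = obs[response_col].to_numpy(dtype=float)
    groups = obs[group_col].to_numpy()
    if np.unique(groups).size < 2:
        raise ValueError("need at least 2 budget levels for the random intercept")
    n = y.size

    def design(names):
        X = np.column_stack([np.ones(n)] + [obs[c].to_numpy(dtype=float) for c in names])
        return X, ["(Intercept)", *names]

    def fit_set(names):
        X, colnames = design(names)
        return fit_mixed_logit(y, X, groups, names=colnames)

    current = covariates
    fit = fit_set(current)
    aicc = fit.aicc(n)
    path = [("full: " + "+".join(current), aicc)]
    while current:
        Xcov = np.column_stack([obs[c].to_numpy(dtype=float) for c in current])
        vifs = dict(zip(current, _vif(Xcov) if len(current) > 1 else [1.0]))
        trials = []
        for c in current:
            f = fit_set([x for x in current if x != c])
            trials.append((c, f, f.aicc(n)))
        improving = [t for t in trials if t[2] < aicc]
        if not improving:
            break
        # prefer removing a high-collinearity covariate when doing so improves
        collinear = [t for t in improving if vifs[t[0]] > vif_threshold]
        drop = (max(collinear, key=lambda t: vifs[t[0]]) if collinear
                else min(improving, key=lambda t: t[2]))
        current = [x for x in current if x != drop[0]]
        fit, aicc = drop[1], drop[2]
        path.append((f"- {drop[0]}", aicc))

    # classification at the 0.5 threshold, using the fitted group intercepts
    X, _ = design(current)
    gcodes = pd.factorize(groups, sort=True)[0]
    eta = X @ fit.beta + fit.u[gcodes]
    pred = (eta > 0).astype(int)
    yi = y.astype(int)
    confusion = np.array(
        [[(pred[yi == a] == b).sum() for b in (0, 1)] for a in (0, 1)]
    )
    accuracy = float((pred == yi).mean())
    table = pd.DataFrame(
        {
            "term": fit.names,
            "estimate": fit.beta,
            "std_error": fit.se,
            "z": fit.zvalues,
            "p_value": fit.pvalues,
        }
    )
    return GLMMReport(
        fit=fit, table=table, retained=current,
        random_intercept_var=fit.sigma2, aicc_path=path,
        accuracy=accuracy, confusion=confusion, n_obs=n,
    )


# ---------------------------------------------------------------------------
# Moran's I
# ---------------------------------------------------------------------------

@dataclass
class MoransIResult:
    I: float
    expected: float
    pvalue: float
    permutations: int


def morans_i(values, sites: SiteTable, permutations: int = 999,
             seed: int | None = 0, alternative: str = "greater") -> MoransIResult:
    """Global Moran's I with inverse-distance, row-standardized weights.

    The permutation p-value shuffles the values across sites (seeded); the
    expectation under the null is -1/(n-1).  ``alternative`` is "greater"
    (clustering), "less", or "two-sided".
    """
    z = np.asarray(values, dtype=float)
    n = z.size
    if n < 3 or len(sites) != n:
        raise ValueError("need >= 3 sites and matching values")
    if z.min() == z.max():
        raise ValueError("constant values: Moran's I undefined")
    d = sites.distances()
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("duplicate coordinates produce infinite weights")
    with np.errstate(divide="ignore"):
        w = 1.0 / d
    np.fill_diagonal(w, 0.0)
    w /= w.sum(axis=1, keepdims=True)  # row-standardized: sum of weights = n

    def stat(x):
        xc = x - x.mean(axis=-1, keepdims=True)
        num = np.einsum("...i,ij,...j->...", xc, w, xc)
        den = np.sum(xc**2, axis=-1)
        return num / den

    I_obs = float(stat(z))
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(z) for _ in range(permutations)])
    I_perm = stat(perms)
    if alternative == "greater":
        p = (1 + np.sum(I_perm >= I_obs)) / (permutations + 1)
    elif alternative == "less":
        p = (1 + np.sum(I_perm <= I_obs)) / (permutations + 1)
    elif alternative == "two-sided":
        p = (1 + np.sum(np.abs(I_perm - expected) >= abs(I_obs - expected))) / (permutations + 1)
    else:
        raise ValueError("alternative must be greater, less or two-sided")
    return MoransIResult(I=I_obs, expected=expected, pvalue=float(p),
                         permutations=permutations)
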