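"""Optional figures mirroring the standard presentation of the analysis:
treatment-time density, climate-deviation scatter, spatial deviation map and
dose-response curves."""

from __future__ import annotations

import numpy as np

from .environment import SiteTable
from .stats import ClimateDeviationReport, DoseResponseFit


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_treatment_density(times, season=(90, 303), ax=None):
    """Gaussian-kernel density of treatment times over the season."""
    ax = _ax(ax)
    from scipy.stats import gaussian_kde

    times = np.asarray(times, dtype=float)
    grid = np.linspace(season[0], season[1], 400)
    if times.size > 1 and times.std() > 0:
        ax.plot(grid, gaussian_kde(times)(grid))
    ax.hist(times, bins=20, density=True, alpha=0.3)
    ax.set_xlabel("day of year")
    ax.set_ylabel("treatment density")
    return ax


def plot_deviation_scatter(report: ClimateDeviationReport, ax=None):
    """Treatment-time climate deviations against the season background."""
    ax = _ax(ax)
    bg_days = np.arange(report.background.size)
    ax.fill_between(bg_days, report.background, alpha=0.3, color="grey",
                    label="season background")
    ax.scatter(report.treatment_days - report.treatment_days.min(),
               report.deviations, color="crimson", zorder=3, label="treatments")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_ylabel(f"% deviation ({report.variable})")
    ax.legend()
    return ax


def plot_spatial_deviation(sites: SiteTable, deviation_pct, counts=None, ax=None):
    """Map of per-site deviation from the homogeneous strategy."""
    ax = _ax(ax)
    size = 30.0 if counts is None else 10 + 8 * np.asarray(counts, float)
    sc = ax.scatter(sites.x, sites.y, c=deviation_pct, s=size, cmap="coolwarm")
    ax.figure.colorbar(sc, ax=ax, label="% deviation from homogeneous")
    ax.set_aspect("equal")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    return ax


def plot_dose_response(fits: dict[str, DoseResponseFit], ax=None):
    """Delta-J against budget fraction with the fitted curves."""
    ax = _ax(ax)
    grid = np.linspace(0, 1, 200)
    for label, fit in fits.items():
        pts = ax.scatter(fit.c, fit.dJ, label=label)
        color = pts.get_facecolor()[0]
        sl, ic = fit.linear_coef
        a, b = fit.exp_coef
        if fit.better_model == "linear":
            ax.plot(grid, sl * grid + ic, color=color)
        else:
            ax.plot(grid, a * (1 - np.exp(-b * grid)), color=color)
    ax.set_xlabel("budget fraction of C_max")
    ax.set_ylabel("ΔJ (%)")
    ax.legend()
    return ax
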