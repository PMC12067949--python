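"""Stochastic search over treatment times and site allocations.

Minimizes the integrated adult population J under the seasonal budget and the
minimal-spacing constraint.  Each restart begins from a random feasible
schedule; every iteration proposes up to ``candidates_per_iter`` mutations
(jittered treatment times, a random swap of treated site-round slots with
untreated ones), evaluates J for each, and adopts the best proposal if it
improves.  Jitter amplitude and swap size shrink geometrically, annealing the
search from coarse to fine.  A restart stops after ``max_iters`` iterations or
after one full iteration without improvement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .environment import ModelParams, SiteTable, VitalRates, WeatherSeries
from .simulator import Simulator, TreatmentSchedule, objective_J

__all__ = ["OptimizerConfig", "OptimizationResult", "RestartResult", "optimize"]


@dataclass
class OptimizerConfig:
    """Search settings.

    Defaults reproduce the study design: 4 rounds, up to 900 candidate
    configurations per iteration, 70 iterations, 25 restarts of which the 10
    best are kept.  ``time_jitter0``/``swap_frac0`` and their decay factors
    control the annealing; ``time_grid`` optionally restricts treatment times
    to a discrete set of candidate days.  ``eval_dt`` is the integration step
    used for candidate evaluation.
    """

    budget: float
    n_rounds: int = 4
    candidates_per_iter: int = 900
    max_iters: int = 70
    n_restarts: int = 25
    keep_best: int = 10
    time_jitter0: float = 30.0
    jitter_decay: float = 0.95
    swap_frac0: float = 0.2
    swap_decay: float = 0.95
    seed: int = 0
    time_grid: np.ndarray | None = None
    eval_dt: float = 0.2
    eval_stiff_target: float = 100.0

    def __post_init__(self):
        if self.candidates_per_iter < 1:
            raise ValueError("candidates_per_iter must be >= 1")
        if not (0 < self.jitter_decay <= 1 and 0 < self.swap_decay <= 1):
            raise ValueError("decay factors must lie in (0, 1]")
        if self.keep_best > self.n_restarts:
            raise ValueError("keep_best cannot exceed n_restarts")
        if self.budget <= 0:
            raise ValueError("budget must be positive")


@dataclass
class RestartResult:
    schedule: TreatmentSchedule
    J: float
    history: list  # accepted J after each iteration (nonincreasing)
    init: dict


@dataclass
class OptimizationResult:
    """Ranked outcome of a multi-restart optimization."""

    restarts: list          # RestartResult, ascending J, truncated to keep_best
    J_uncontrolled: float
    config: OptimizerConfig
    n_evaluations: int

    @property
    def best(self) -> RestartResult:
        return self.restarts[0]

    @property
    def best_schedule(self) -> TreatmentSchedule:
        return self.restarts[0].schedule

    @property
    def best_J(self) -> float:
        return self.restarts[0].J

    @property
    def schedules(self) -> list:
        return [r.schedule for r in self.restarts]


# ---------------------------------------------------------------------------
# Schedule sampling and mutation
# ---------------------------------------------------------------------------

def _snap(times: np.ndarray, grid: np.ndarray | None) -> np.ndarray:
    times = np.floor(times)  # start of the containing day
    if grid is not None:
        idx = np.abs(times[:, None] - grid[None, :]).argmin(axis=1)
        times = grid[idx].astype(float)
    return times


def _feasible_times(rng, n, lo, hi, spacing, grid) -> np.ndarray:
    """Rejection-sample sorted times in [lo, hi] with the minimal spacing."""
    for _ in range(200):
        if grid is not None:
            if grid.size < n:
                raise ValueError("time grid smaller than the number of rounds")
            t = np.sort(rng.choice(grid, size=n, replace=False).astype(float))
        else:
            t = np.sort(_snap(rng.uniform(lo, hi, size=n), None))
        if n == 1 or np.all(np.diff(t) >= spacing):
            return t
    # fall back to an evenly spaced feasible placement
    if grid is not None:
        raise ValueError("no feasible spacing found on the supplied time grid")
    t = np.linspace(lo, hi, n)
    return _snap(t, None)


def _random_allocation(rng, n_rounds, doses, budget) -> np.ndarray:
    """Random budget-respecting allocation: shuffle all slots, greedy fill."""
    N = doses.size
    xi = np.zeros((n_rounds, N), dtype=np.int8)
    slots = [(k, i) for k in range(n_rounds) for i in range(N)]
    rng.shuffle(slots)
    used = 0.0
    for k, i in slots:
        if used + doses[i] <= budget + 1e-9:
            xi[k, i] = 1
            used += doses[i]
    return xi


def _mutate(rng, sch: TreatmentSchedule, jitter, swap_frac, lo, hi, spacing,
            grid, budget) -> TreatmentSchedule:
    n = sch.n_rounds
    doses = sch.doses
    # --- jitter times, then repair ordering / spacing / bounds
    t = np.sort(sch.times + rng.uniform(-jitter, jitter, size=n))
    t = np.clip(t, lo, hi)
    for k in range(1, n):
        t[k] = max(t[k], t[k - 1] + spacing)
    t = _snap(t, grid)
    ok = (n == 1 or np.all(np.diff(t) >= spacing - 1e-9)) and t[-1] <= hi + 1e-9
    if not ok:
        t = _feasible_times(rng, n, lo, hi, spacing, grid)
    # --- swap a subset of treated slots with untreated ones
    xi = sch.xi.copy()
    treated = np.argwhere(xi == 1)
    if treated.shape[0] > 0 and swap_frac > 0:
        n_swap = max(1, math.ceil(swap_frac * treated.shape[0]))
        n_swap = min(n_swap, treated.shape[0])
        drop = treated[rng.choice(treated.shape[0], size=n_swap, replace=False)]
        xi[drop[:, 0], drop[:, 1]] = 0
    used = float((xi * doses).sum())
    untreated = np.argwhere(xi == 0)
    for j in rng.permutation(untreated.shape[0]):
        k, i = untreated[j]
        if used + doses[i] <= budget + 1e-9:
            xi[k, i] = 1
            used += doses[i]
    return TreatmentSchedule(t, xi, doses)


# ---------------------------------------------------------------------------
# Main loop
# ---------------------------------------------------------------------------

def optimize(sites: SiteTable, weather: WeatherSeries, rates: VitalRates,
             params: ModelParams, config: OptimizerConfig,
             init: dict[str, np.ndarray] | None = None,
             on_candidate: Callable[[TreatmentSchedule, float], None] | None = None,
             ) -> OptimizationResult:
    """Run the multi-restart stochastic search.

    ``init`` fixes the initial state for every restart (useful for matched
    strategy comparisons); when omitted, each restart draws its own randomized
    initial conditions from the seeded stream.  ``on_candidate`` is called with
    every evaluated (schedule, J) pair — an audit hook.

    With identical seeds the result is bitwise reproducible.
    """
    from .simulator import default_initial_conditions

    doses = sites.require_doses()
    if config.budget < doses.min():
        raise ValueError("budget below the smallest site dose: only the empty schedule is feasible")
    sim = Simulator(sites, weather, rates, params, dt=config.eval_dt,
                    stiff_target=config.eval_stiff_target)
    lo, hi = sim.season()
    if lo + (config.n_rounds - 1) * params.t_min_spacing > hi:
        raise ValueError("minimal spacing times rounds exceeds the season window")
    grid = None if config.time_grid is None else np.asarray(config.time_grid, dtype=float)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_restarts)
    n_evals = 0
    restarts = []
    J0_cache: dict[int, float] = {}

    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        init_r = init if init is not None else default_initial_conditions(
            sites, weather, params, rng
        )
        # shared uncontrolled segment up to the season start: evaluate every
        # candidate only over [season_start, end] from the frozen state there
        pre = sim.run(None, init_r, t0=0, t1=lo)
        J_pre = objective_J(pre)
        state_lo = {"L": pre.L[-1], "A": pre.A[-1], "c": pre.c[-1]}

        def J_of(sch: TreatmentSchedule) -> float:
            nonlocal n_evals
            seg = sim.run(sch, state_lo, t0=lo, validate_schedule=False)
            J = J_pre + objective_J(seg)
            n_evals += 1
            if on_candidate is not None:
                on_candidate(sch, J)
            return J

        J_unc = J_pre + objective_J(sim.run(None, state_lo, t0=lo))

        times = _feasible_times(rng, config.n_rounds, lo, hi, params.t_min_spacing, grid)
        xi = _random_allocation(rng, config.n_rounds, doses, config.budget)
        current = TreatmentSchedule(times, xi, doses)
        J_cur = J_of(current)
        history = [J_cur]

        jitter = config.time_jitter0
        swap = config.swap_frac0
        for _ in range(config.max_iters):
            best_c, best_J = None, J_cur
            for _ in range(config.candidates_per_iter):
                cand = _mutate(rng, current, jitter, swap, lo, hi,
                               params.t_min_spacing, grid, config.budget)
                Jc = J_of(cand)
                if Jc < best_J:
                    best_c, best_J = cand, Jc
            if best_c is None:
                break  # stagnation: a full iteration without improvement
            current, J_cur = best_c, best_J
            history.append(J_cur)
            jitter *= config.jitter_decay
            swap *= config.swap_decay
        restarts.append(RestartResult(current, J_cur, history, init_r))
        J0_cache[r] = J_unc

    order = np.argsort([r.J for r in restarts], kind="stable")
    ranked = [restarts[i] for i in order[: config.keep_best]]
    J_unc_best = J0_cache[int(order[0])]
    return OptimizationResult(ranked, J_unc_best, config, n_evals)
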