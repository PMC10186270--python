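"""Goodness-of-fit metrics and genetic-algorithm parameter estimation.

Whole-plant parameters are estimated by minimising a variance-normalised
sum-of-squares criterion over seven observed variables (leaf, stem, root
and fruit dry weights, fruit fresh weight, fruit soluble sugar and starch
concentrations) with a seeded real-coded genetic algorithm (tournament
selection, blend crossover, Gaussian mutation, elitism).  Gas-exchange
parameters are fitted separately by the two utility fitters at the bottom
(two-limb A-Ci regression for Vcmax/Jmax; Nelder-Mead for the conductance
reduction factors), mirroring a two-stage protocol in which leaf-level
parameters are fixed before the whole-plant stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .drivers import EnvForcing
from .params import InitialState, ParameterSet, PhotoParams
from .simulate import SimulationResult, run_season

__all__ = [
    "ObservationSet",
    "CalibrationSpec",
    "GAResult",
    "mae",
    "rrmse",
    "objective_criterion",
    "calibrate_ga",
    "fit_vcmax_jmax",
    "fit_jarvis_gsmax",
]

#: the seven variables entering the whole-plant criterion
CRITERION_VARIABLES = ("DW_leaf", "DW_stem", "DW_root", "DW_fruit",
                      "FW_fruit", "SSc", "Stac")

#: observation variable -> simulated trajectory column
_SIM_COLUMN = {
    "DW_leaf": "DW_leaf", "DW_stem": "DW_stem", "DW_root": "DW_root",
    "DW_fruit": "DW", "FW_fruit": "FW", "SSc": "SSc", "Stac": "Stac",
    "LA": "LA",
}


@dataclass
class ObservationSet:
    """Long-format observations: (daa, variable, value, replicate)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"daa", "variable", "value", "replicate"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"observation table missing columns: {sorted(missing)}")
        if (self.df["value"] < 0).any():
            raise ValueError("observation values must be >= 0")
        unknown = set(self.df["variable"]) - set(_SIM_COLUMN)
        if unknown:
            raise ValueError(f"unknown observation variables: {sorted(unknown)}")

    @classmethod
    def from_csv(cls, path: str) -> "ObservationSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str) -> None:
        self.df.to_csv(path, index=False)

    def replicate_means(self) -> pd.DataFrame:
        """Mean over replicates per (variable, daa)."""
        return (self.df.groupby(["variable", "daa"], as_index=False)["value"]
                .mean())


def mae(observed: Sequence[float], simulated: Sequence[float]) -> float:
    """Mean absolute error, in the units of the inputs."""
    o = np.asarray(observed, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if o.shape != s.shape or o.size == 0:
        raise ValueError("observed and simulated must be same-length, non-empty")
    return float(np.mean(np.abs(o - s)))


def rrmse(observed: Sequence[float], simulated: Sequence[float]) -> float:
    """Root-mean-square error divided by the observed mean (dimensionless)."""
    o = np.asarray(observed, dtype=float)
    s = np.asarray(simulated, dtype=float)
    if o.shape != s.shape or o.size == 0:
        raise ValueError("observed and simulated must be same-length, non-empty")
    om = float(np.mean(o))
    if om <= 0:
        raise ValueError("mean of observed values must be > 0")
    return float(np.sqrt(np.mean((o - s) ** 2)) / om)


def _match_simulated(sim: SimulationResult, variable: str,
                     daas: np.ndarray, max_gap: float = 0.5) -> np.ndarray:
    col = _SIM_COLUMN[variable]
    sim_daa = sim.df["daa"].to_numpy()
    sim_val = sim.df[col].to_numpy()
    idx = np.searchsorted(sim_daa, daas)
    idx = np.clip(idx, 1, len(sim_daa) - 1)
    left = idx - 1
    choose_left = (daas - sim_daa[left]) <= (sim_daa[idx] - daas)
    nearest = np.where(choose_left, left, idx)
    gap = np.abs(sim_daa[nearest] - daas)
    if (gap > max_gap).any():
        raise ValueError(
            f"no simulated time point within {max_gap} d of an observation "
            f"for {variable!r} (worst gap {gap.max():.2f} d)")
    return sim_val[nearest]


def objective_criterion(obs: ObservationSet, sim: SimulationResult,
                        ddof: int = 1) -> float:
    """Variance-normalised squared-error criterion over the seven
    whole-plant variables.

    For each variable v present in the observations:
    sum((y_o - y_s)^2) / var(y_o), with observations matched to the nearest
    simulated time point (within 0.5 day) and the variance taken over the
    per-time replicate means (``ddof=1`` by default; set 0 for the
    population convention).  Variables not observed contribute nothing;
    perfectly fitted variables contribute zero.
    """
    means = obs.replicate_means()
    total = 0.0
    for var, grp in means.groupby("variable"):
        if var not in CRITERION_VARIABLES:
            continue
        vals = grp["value"].to_numpy(dtype=float)
        var_o = float(np.var(vals, ddof=ddof)) if len(vals) > ddof else 0.0
        if var_o <= 0:
            raise ValueError(f"degenerate observations for {var!r} (zero variance)")
        sim_vals = _match_simulated(sim, var, grp["daa"].to_numpy(dtype=float))
        total += float(np.sum((vals - sim_vals) ** 2)) / var_o
    return total


# ---------------------------------------------------------------------------
# Genetic algorithm


@dataclass
class CalibrationSpec:
    """Free parameters (dotted ``block.field`` names) with bounds, and the
    GA settings.  The seed is mandatory: runs are reproducible."""

    free: dict[str, tuple[float, float]]
    seed: int
    population: int = 40
    generations: int = 30
    crossover_rate: float = 0.9
    mutation_rate: float = 0.15
    mutation_sigma: float = 0.10     # fraction of each bound range
    sigma_anneal: float = 0.05       # final sigma as a fraction of the initial
    blend_alpha: float = 0.5
    tournament: int = 3
    elitism: int = 1

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.free.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bad bounds for {name!r}: ({lo}, {hi})")


@dataclass
class GAResult:
    best_params: dict[str, float]
    best_criterion: float
    trace: list[float]               # best-so-far criterion per generation
    n_evaluations: int
    failures: list[str] = field(default_factory=list)


def _ga_minimise(fitness: Callable[[np.ndarray], float],
                 bounds: np.ndarray, spec: CalibrationSpec
                 ) -> tuple[np.ndarray, float, list[float], int, list[str]]:
    rng = np.random.default_rng(spec.seed)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    npar = len(lo)
    pop = lo + rng.random((spec.population, npar)) * span
    failures: list[str] = []
    n_eval = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            return float(fitness(x))
        except Exception as exc:  # failed simulation = unfit individual
            failures.append(f"{exc.__class__.__name__}: {exc}")
            return math.inf

    fit = np.array([evaluate(x) for x in pop])
    if not np.isfinite(fit).any() and spec.generations == 0:
        raise RuntimeError("all GA evaluations failed: " + "; ".join(failures[:5]))
    trace = [float(fit.min())]
    for gen in range(spec.generations):
        # geometric annealing of the mutation scale: coarse exploration in
        # early generations, fine local refinement at the end
        frac = gen / max(spec.generations - 1, 1)
        sigma = spec.mutation_sigma * spec.sigma_anneal ** frac
        order = np.argsort(fit)
        new_pop = [pop[order[i]].copy() for i in range(spec.elitism)]
        while len(new_pop) < spec.population:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                cand = rng.integers(0, spec.population, spec.tournament)
                parents.append(pop[cand[np.argmin(fit[cand])]])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < spec.crossover_rate:
                # BLX-alpha blend crossover
                cmin = np.minimum(c1, c2)
                cmax = np.maximum(c1, c2)
                d = cmax - cmin
                low = cmin - spec.blend_alpha * d
                high = cmax + spec.blend_alpha * d
                c1 = low + rng.random(npar) * (high - low)
                c2 = low + rng.random(npar) * (high - low)
            for child in (c1, c2):
                mask = rng.random(npar) < spec.mutation_rate
                child[mask] += rng.normal(0.0, sigma, mask.sum()) * span[mask]
                np.clip(child, lo, hi, out=child)
                if len(new_pop) < spec.population:
                    new_pop.append(child)
        pop = np.array(new_pop)
        fit = np.array([evaluate(x) for x in pop])
        # elitism guarantees a non-increasing best-so-far trace
        trace.append(min(trace[-1], float(fit.min())))
    if not np.isfinite(fit).any():
        raise RuntimeError("all GA evaluations failed: " + "; ".join(failures[:5]))
    # with elitism >= 1 and a deterministic fitness the best-ever vector is
    # still in the final population
    best = int(np.argmin(fit))
    return pop[best], float(fit[best]), trace, n_eval, failures


def calibrate_ga(obs: ObservationSet, spec: CalibrationSpec,
                 forcing: list[EnvForcing], fixed_params: ParameterSet,
                 init: InitialState | None = None, n_sub: int = 1,
                 ddof: int = 1) -> GAResult:
    """Search the bound box for the parameter vector minimising the
    whole-plant criterion; reproducible under ``spec.seed``."""
    names = list(spec.free)
    bounds = np.array([spec.free[n] for n in names], dtype=float)

    def fitness(x: np.ndarray) -> float:
        params = fixed_params.replace(**dict(zip(names, x)))
        sim = run_season(forcing, params, init, n_sub=n_sub, record="light")
        return objective_criterion(obs, sim, ddof=ddof)

    best_x, best_f, trace, n_eval, failures = _ga_minimise(fitness, bounds, spec)
    return GAResult(best_params=dict(zip(names, map(float, best_x))),
                    best_criterion=best_f, trace=trace,
                    n_evaluations=n_eval, failures=failures)


# ---------------------------------------------------------------------------
# Leaf-level stage-one fitters (utilities)


def fit_vcmax_jmax(ci: Sequence[float], a: Sequence[float], p: PhotoParams
                   ) -> tuple[float, float, float]:
    """Fit Vcmax and Jmax from an A-Ci curve by two-limb change-point least
    squares: for every candidate split of the (sorted) curve, the low-Ci
    points are regressed on the Rubisco-limited predictor and the high-Ci
    points on the RuBP-limited predictor (both linear through the origin in
    the capacity), and the split with the smallest total residual wins.
    Returns (Vcmax, Jmax, SSE).
    """
    ci_arr = np.asarray(ci, dtype=float)
    a_arr = np.asarray(a, dtype=float) + p.Rd   # gross carboxylation
    order = np.argsort(ci_arr)
    ci_arr, a_arr = ci_arr[order], a_arr[order]
    if len(ci_arr) < 4:
        raise ValueError("need at least 4 A-Ci points")
    kco = p.Kc * (1.0 + p.O2 / p.Ko)
    x_c = (ci_arr - p.gamma_star) / (ci_arr + kco)          # * Vcmax
    x_j = (ci_arr - p.gamma_star) / (4.0 * (ci_arr + 2.0 * p.gamma_star))  # * Jmax
    best = None
    for split in range(2, len(ci_arr) - 1):
        vc = float(x_c[:split] @ a_arr[:split] / (x_c[:split] @ x_c[:split]))
        jm = float(x_j[split:] @ a_arr[split:] / (x_j[split:] @ x_j[split:]))
        pred = np.minimum(vc * x_c, jm * x_j)
        sse = float(np.sum((a_arr - pred) ** 2))
        if best is None or sse < best[2]:
            best = (vc, jm, sse)
    assert best is not None
    return best


def fit_jarvis_gsmax(envs: list[EnvForcing], gs_obs: Sequence[float],
                     base: ParameterSet,
                     free: Sequence[str] = ("gs_max", "k_vpd", "T_opt"),
                     ) -> dict[str, float]:
    """Least-squares fit of selected stomatal parameters to observed
    conductances (Nelder-Mead).  Returns the fitted name -> value map."""
    from dataclasses import replace as dc_replace

    from .gas_exchange import jarvis_conductance

    gs_arr = np.asarray(gs_obs, dtype=float)
    x0 = np.array([getattr(base.stomatal, n) for n in free], dtype=float)

    def loss(x: np.ndarray) -> float:
        sp = dc_replace(base.stomatal, **dict(zip(free, x)))
        if sp.gs_max <= 0:
            return 1e12
        pred = np.array([jarvis_conductance(e, sp) for e in envs])
        return float(np.sum((pred - gs_arr) ** 2))

    res = minimize(loss, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 4000})
    return dict(zip(free, map(float, res.x)))
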