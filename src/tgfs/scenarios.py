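"""Factorial nitrogen x irrigation sustainability scenarios under future
climate, percentage-change metrics and Pareto-front selection.

Each scenario scales the reference fertilisation and irrigation schedules
by a multiplier between 100% and 60% in 5% steps (9 x 9 = 81 scenarios),
simulates every available climate year, and summarises mature-fruit fresh
weight and soluble sugar concentration as percentage changes relative to
the reference condition in the first year.  The trade-off between the two
objectives is resolved by the set of non-dominated scenarios.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .drivers import EnvForcing
from .params import InitialState, ParameterSet
from .simulate import run_season, seasonal_aggregates

__all__ = [
    "ScenarioSpec",
    "ScenarioOutcome",
    "scenario_grid",
    "delta_metric",
    "pareto_front",
    "apply_multipliers",
    "run_sweep",
]

log = logging.getLogger(__name__)

MULTIPLIER_LEVELS = tuple(round(1.00 - 0.05 * i, 2) for i in range(9))


@dataclass(frozen=True)
class ScenarioSpec:
    """One N x water input combination (multipliers of the reference)."""

    N_mult: float
    W_mult: float

    def __post_init__(self) -> None:
        for m in (self.N_mult, self.W_mult):
            if not any(abs(m - lvl) < 1e-9 for lvl in MULTIPLIER_LEVELS):
                raise ValueError(
                    f"multiplier {m} not on the 1.00..0.60 step-0.05 grid")


@dataclass
class ScenarioOutcome:
    spec: ScenarioSpec
    FW: float                # g, final-window mean of the last year(s)
    SSc: float               # g / 100 g FW
    dFW_pct: float
    dSSc_pct: float
    failed: bool = False


def scenario_grid() -> list[ScenarioSpec]:
    """The full 9 x 9 factorial of N and water multipliers (81 scenarios)."""
    return [ScenarioSpec(n, w) for n in MULTIPLIER_LEVELS
            for w in MULTIPLIER_LEVELS]


def delta_metric(final_mean: float, initial_ref: float) -> float:
    """Percentage change 100 * (final - reference) / reference."""
    if initial_ref <= 0:
        raise ValueError("reference value must be > 0")
    return 100.0 * (final_mean - initial_ref) / initial_ref


def pareto_front(outcomes: list[ScenarioOutcome]) -> list[ScenarioOutcome]:
    """Non-dominated subset maximising (dFW_pct, dSSc_pct).

    An outcome is dominated if another is at least as good in both
    objectives and strictly better in one; ties in both objectives are all
    kept.  Idempotent: the front of a front is itself.
    """
    if not outcomes:
        raise ValueError("empty outcome list")
    kept = []
    for o in outcomes:
        dominated = any(
            (q.dFW_pct >= o.dFW_pct and q.dSSc_pct >= o.dSSc_pct)
            and (q.dFW_pct > o.dFW_pct or q.dSSc_pct > o.dSSc_pct)
            for q in outcomes)
        if not dominated:
            kept.append(o)
    return kept


def apply_multipliers(forcing: list[EnvForcing], spec: ScenarioSpec,
                      theta_w: float, mode: str = "deficit") -> list[EnvForcing]:
    """Scale a season's soil N and soil water schedules by the scenario.

    N is multiplied directly (it only enters the conductance reduction
    factor).  For water, ``deficit`` mode (default) scales the excess of
    theta over the wilting point, so reduced irrigation cannot push the
    soil below wilting; ``plain`` mode scales theta itself.
    """
    out = []
    for rec in forcing:
        if mode == "deficit":
            theta = theta_w + spec.W_mult * max(rec.theta - theta_w, 0.0)
        elif mode == "plain":
            theta = spec.W_mult * rec.theta
        else:
            raise ValueError(f"unknown water scaling mode {mode!r}")
        out.append(dataclasses.replace(rec, theta=theta, N=spec.N_mult * rec.N))
    return out


def run_sweep(grid: list[ScenarioSpec], climate_years: dict[int, list[EnvForcing]],
              params: ParameterSet, init: InitialState | None = None,
              window_years: int = 5, mode: str = "deficit",
              n_sub: int = 1) -> pd.DataFrame:
    """Simulate every scenario over every climate year and assemble the
    outcome table.

    The reference value is the (1.00, 1.00) scenario in the first climate
    year; each scenario's final value is the mean of its last
    ``window_years`` years.  A failing scenario is recorded as a failed
    row and the sweep continues.  Columns: N_mult, W_mult, FW, SSc,
    dFW_pct, dSSc_pct, failed, on_pareto_front.
    """
    if not climate_years:
        raise ValueError("no climate years supplied")
    years = sorted(climate_years)
    theta_w = params.stomatal.theta_w
    ref_spec = ScenarioSpec(1.00, 1.00)
    ref_forcing = apply_multipliers(climate_years[years[0]], ref_spec,
                                    theta_w, mode)
    ref = seasonal_aggregates(run_season(ref_forcing, params, init,
                                         n_sub=n_sub, record="light"))
    ref_fw, ref_ssc = ref["final_FW"], ref["final_SSc"]

    outcomes: list[ScenarioOutcome] = []
    for spec in grid:
        try:
            finals_fw, finals_ssc = [], []
            for year in years[-window_years:]:
                scen_forcing = apply_multipliers(climate_years[year], spec,
                                                 theta_w, mode)
                agg = seasonal_aggregates(
                    run_season(scen_forcing, params, init, n_sub=n_sub,
                               record="light"))
                finals_fw.append(agg["final_FW"])
                finals_ssc.append(agg["final_SSc"])
            fw = float(np.mean(finals_fw))
            ssc = float(np.mean(finals_ssc))
            outcomes.append(ScenarioOutcome(
                spec, fw, ssc,
                delta_metric(fw, ref_fw), delta_metric(ssc, ref_ssc)))
        except Exception as exc:
            log.warning("scenario %s failed: %s", spec, exc)
            outcomes.append(ScenarioOutcome(spec, math.nan, math.nan,
                                            math.nan, math.nan, failed=True))
    ok = [o for o in outcomes if not o.failed]
    front = set(id(o) for o in pareto_front(ok)) if ok else set()
    rows = [{
        "N_mult": o.spec.N_mult, "W_mult": o.spec.W_mult,
        "FW": o.FW, "SSc": o.SSc,
        "dFW_pct": o.dFW_pct, "dSSc_pct": o.dSSc_pct,
        "failed": o.failed, "on_pareto_front": id(o) in front,
    } for o in outcomes]
    return pd.DataFrame(rows)

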