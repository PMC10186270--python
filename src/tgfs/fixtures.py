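"""Synthetic pseudo-observations and treatment bundles.

The original experiments behind the model (pot-grown tomato under factorial
nitrogen x irrigation treatments) are not distributed, so this module makes
the calibration and scenario machinery testable end to end: it simulates a
"true" plant with known parameters, samples the seven calibration variables
on a realistic measurement schedule with multiplicative lognormal noise,
and provides the four canonical treatment forcing bundles (three N levels
under full irrigation plus a moderate-N deficit-irrigation treatment).
All outputs are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CRITERION_VARIABLES, ObservationSet, _SIM_COLUMN
from .drivers import EnvForcing, SeasonConfig, generate_synthetic_season
from .params import InitialState, ParameterSet
from .simulate import run_season

__all__ = [
    "FixtureConfig",
    "pseudo_observations",
    "default_experiment_suite",
]

#: soil mineral N levels (mg kg-1) of the low / moderate / high treatments
TREATMENT_N = {"N1": 60.0, "N2": 120.0, "N3": 180.0}
#: soil water content of full irrigation and of the deficit treatment
THETA_FULL = 0.32
THETA_DEFICIT = 0.18


@dataclass
class FixtureConfig:
    """Pseudo-observation sampling settings.

    Default schedule: every 7 days from 10 days after anthesis, matching
    destructive-harvest campaigns at 5-10 day intervals.  ``cv`` is the
    per-variable coefficient of variation of the multiplicative lognormal
    measurement noise.
    """

    seed: int
    daa_list: list[float] = field(default_factory=list)
    cv: dict[str, float] | float = 0.05
    replicates: int = 3
    variables: tuple[str, ...] = CRITERION_VARIABLES
    true_overrides: dict[str, float] = field(default_factory=dict)

    def schedule(self, n_days: int) -> list[float]:
        if self.daa_list:
            return list(self.daa_list)
        return [float(d) for d in range(10, n_days, 7)]

    def cv_for(self, variable: str) -> float:
        if isinstance(self.cv, dict):
            return float(self.cv.get(variable, 0.05))
        return float(self.cv)


def pseudo_observations(cfg: FixtureConfig, forcing: list[EnvForcing],
                        params: ParameterSet,
                        init: InitialState | None = None,
                        n_sub: int = 1) -> ObservationSet:
    """Simulate with the true parameters and sample noisy observations.

    Noise is multiplicative lognormal with unit mean and the configured CV
    (sigma^2 = ln(1 + CV^2)), preserving positivity; ``cv = 0`` returns the
    simulated values exactly.
    """
    if cfg.cv_for("any") < 0 or cfg.replicates < 1:
        raise ValueError("cv must be >= 0 and replicates >= 1")
    true_params = params.replace(**cfg.true_overrides)
    sim = run_season(forcing, true_params, init, n_sub=n_sub, record="light")
    rng = np.random.default_rng(cfg.seed)
    sim_daa = sim.df["daa"].to_numpy()
    n_days = forcing[-1].daa
    rows = []
    for var in cfg.variables:
        col = _SIM_COLUMN[var]
        cv = cfg.cv_for(var)
        sigma = np.sqrt(np.log1p(cv * cv))
        for daa in cfg.schedule(int(n_days) + 1):
            idx = int(np.argmin(np.abs(sim_daa - daa)))
            truth = float(sim.df[col].iloc[idx])
            for rep in range(cfg.replicates):
                if cv > 0:
                    noise = rng.lognormal(-0.5 * sigma * sigma, sigma)
                else:
                    noise = 1.0
                rows.append({"daa": daa, "variable": var,
                             "value": truth * noise, "replicate": rep})
    return ObservationSet(pd.DataFrame(rows))


def default_experiment_suite(n_days: int = 60, seed: int = 20150601
                             ) -> dict[str, list[EnvForcing]]:
    """The four canonical treatment forcing bundles.

    Three nitrogen levels under full irrigation (N1Wck < N2Wck < N3Wck,
    pointwise ordered soil N) plus moderate N with a whole-season
    irrigation deficit (N2DI, identical to N2Wck except the soil water
    schedule).  All bundles share the same weather realisation (same seed),
    so the treatments are controlled contrasts.
    """
    bundles = {}
    for name, n_level in (("N1Wck", TREATMENT_N["N1"]),
                          ("N2Wck", TREATMENT_N["N2"]),
                          ("N3Wck", TREATMENT_N["N3"])):
        cfg = SeasonConfig(n_days=n_days, seed=seed, N_mean=n_level,
                           theta_mean=THETA_FULL)
        bundles[name] = generate_synthetic_season(cfg)
    cfg = SeasonConfig(n_days=n_days, seed=seed, N_mean=TREATMENT_N["N2"],
                       theta_mean=THETA_DEFICIT, theta_amp=0.0)
    bundles["N2DI"] = generate_synthetic_season(cfg)
    return bundles
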