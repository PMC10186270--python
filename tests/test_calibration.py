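from dataclasses import replace as dataclasses_replace

import numpy as np
import pandas as pd
import pytest

from tgfs.calibration import (CalibrationSpec, GAResult, ObservationSet,
                              _ga_minimise, fit_vcmax_jmax, mae,
                              objective_criterion, rrmse)
from tgfs.params import PhotoParams


class TestMae:
    def test_identical_vectors(self):
        assert mae([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_value(self):
        assert mae([1, 2, 3], [2, 2, 2]) == pytest.approx(2 / 3)

    def test_symmetric(self):
        assert mae([1, 5], [4, 2]) == mae([4, 2], [1, 5])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mae([1, 2], [1])


class TestRrmse:
    def test_identical_vectors(self):
        assert rrmse([10, 10], [10, 10]) == 0.0

    def test_hand_value(self):
        assert rrmse([10, 10], [11, 9]) == pytest.approx(0.1)

    def test_scale_invariance(self):
        o, s = np.array([3.0, 5, 9]), np.array([4.0, 4, 8])
        assert rrmse(o, s) == pytest.approx(rrmse(10 * o, 10 * s))

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            rrmse([0, 0], [1, 1])


def _fake_sim(series: dict[str, tuple[list[float], list[float]]]):
    """A stand-in simulation result carrying prescribed trajectories."""
    from tgfs.simulate import SimulationResult

    daa = sorted({d for daas, _ in series.values() for d in daas})
    df = pd.DataFrame({"daa": daa})
    for col, (daas, vals) in series.items():
        df[col] = np.interp(daa, daas, vals)
    return SimulationResult(df=df, initial={}, params=None, Fn=12.0)


class TestObjectiveCriterion:
    def _obs(self, var, daas, values):
        return ObservationSet(pd.DataFrame(
            {"daa": daas, "variable": var, "value": values,
             "replicate": [0] * len(daas)}))

    def test_perfect_fit_is_zero(self):
        obs = self._obs("DW_leaf", [10.0, 20.0], [3.0, 6.0])
        sim = _fake_sim({"DW_leaf": ([10.0, 20.0], [3.0, 6.0])})
        assert objective_criterion(obs, sim) == 0.0

    def test_hand_value_sample_variance(self):
        # o=(0,2): var (ddof=1) = 2; s=(1,1): criterion = (1+1)/2 = 1
        obs = self._obs("DW_leaf", [10.0, 20.0], [0.0, 2.0])
        sim = _fake_sim({"DW_leaf": ([10.0, 20.0], [1.0, 1.0])})
        assert objective_criterion(obs, sim) == pytest.approx(1.0)

    def test_population_variance_option(self):
        obs = self._obs("DW_leaf", [10.0, 20.0], [0.0, 2.0])
        sim = _fake_sim({"DW_leaf": ([10.0, 20.0], [1.0, 1.0])})
        assert objective_criterion(obs, sim, ddof=0) == pytest.approx(2.0)

    def test_perfectly_fitted_extra_variable_changes_nothing(self):
        obs1 = self._obs("DW_leaf", [10.0, 20.0], [0.0, 2.0])
        both = pd.concat([
            obs1.df,
            self._obs("SSc", [10.0, 20.0], [1.0, 3.0]).df])
        sim = _fake_sim({"DW_leaf": ([10.0, 20.0], [1.0, 1.0]),
                         "SSc": ([10.0, 20.0], [1.0, 3.0])})
        assert objective_criterion(ObservationSet(both), sim) == pytest.approx(
            objective_criterion(obs1, sim))

    def test_unit_rescaling_invariance(self):
        obs = self._obs("DW_leaf", [10.0, 20.0, 30.0], [2.0, 5.0, 7.0])
        sim = _fake_sim({"DW_leaf": ([10.0, 20.0, 30.0], [2.5, 4.0, 8.0])})
        c1 = objective_criterion(obs, sim)
        obs10 = self._obs("DW_leaf", [10.0, 20.0, 30.0], [20.0, 50.0, 70.0])
        sim10 = _fake_sim({"DW_leaf": ([10.0, 20.0, 30.0], [25.0, 40.0, 80.0])})
        assert objective_criterion(obs10, sim10) == pytest.approx(c1)

    def test_degenerate_observations_rejected(self):
        obs = self._obs("DW_leaf", [10.0, 20.0], [2.0, 2.0])
        sim = _fake_sim({"DW_leaf": ([10.0, 20.0], [1.0, 1.0])})
        with pytest.raises(ValueError):
            objective_criterion(obs, sim)

    def test_matching_beyond_half_day_rejected(self):
        obs = self._obs("DW_leaf", [40.0], [2.0])
        sim = _fake_sim({"DW_leaf": ([10.0, 20.0], [1.0, 1.0])})
        with pytest.raises(ValueError):
            objective_criterion(obs, sim)


class TestGeneticAlgorithm:
    """The GA core exercised on cheap analytic fitness landscapes."""

    BOUNDS = np.array([[-2.0, 2.0], [-1.0, 3.0]])

    @staticmethod
    def _sphere(x):
        return float((x[0] - 0.5) ** 2 + (x[1] - 1.5) ** 2)

    def _spec(self, **kw):
        settings = dict(free={"a": (-2.0, 2.0), "b": (-1.0, 3.0)}, seed=5,
                        population=24, generations=25)
        settings.update(kw)
        return CalibrationSpec(**settings)

    def test_finds_analytic_minimum(self):
        x, f, trace, n, _ = _ga_minimise(self._sphere, self.BOUNDS, self._spec())
        assert f < 1e-2
        assert np.allclose(x, [0.5, 1.5], atol=0.15)

    def test_zero_generations_returns_best_of_initial_population(self):
        spec = self._spec(generations=0)
        x, f, trace, n, _ = _ga_minimise(self._sphere, self.BOUNDS, spec)
        assert n == spec.population and len(trace) == 1
        rng = np.random.default_rng(spec.seed)
        lo, hi = self.BOUNDS[:, 0], self.BOUNDS[:, 1]
        pop = lo + rng.random((spec.population, 2)) * (hi - lo)
        best = min(self._sphere(p) for p in pop)
        assert f == pytest.approx(best)

    def test_seed_reproducibility(self):
        r1 = _ga_minimise(self._sphere, self.BOUNDS, self._spec())
        r2 = _ga_minimise(self._sphere, self.BOUNDS, self._spec())
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]

    def test_trace_non_increasing(self):
        _, _, trace, _, _ = _ga_minimise(self._sphere, self.BOUNDS, self._spec())
        assert all(b <= a for a, b in zip(trace, trace[1:]))

    def test_respects_bounds(self):
        x, *_ = _ga_minimise(lambda x: -x[0] - x[1], self.BOUNDS, self._spec())
        assert self.BOUNDS[0, 0] <= x[0] <= self.BOUNDS[0, 1]
        assert self.BOUNDS[1, 0] <= x[1] <= self.BOUNDS[1, 1]

    def test_failing_evaluations_are_recorded_and_skipped(self):
        def flaky(x):
            if x[0] < 0:
                raise RuntimeError("simulation diverged")
            return self._sphere(x)

        x, f, _, _, failures = _ga_minimise(flaky, self.BOUNDS, self._spec())
        assert failures and x[0] >= 0

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            CalibrationSpec(free={"a": (1.0, 1.0)}, seed=0)


class TestJarvisFitter:
    def test_recovers_gsmax_and_vpd_slope(self, make_env):
        from tgfs.calibration import fit_jarvis_gsmax
        from tgfs.gas_exchange import jarvis_conductance
        from tgfs.params import default_parameters

        base = default_parameters()
        truth = dataclasses_replace(base.stomatal, gs_max=0.40, k_vpd=0.5)
        rng = np.random.default_rng(6)
        envs = [make_env(Ta=rng.uniform(15, 35), RH=rng.uniform(40, 90),
                         theta=rng.uniform(0.2, 0.4))
                for _ in range(40)]
        gs_obs = [jarvis_conductance(e, truth) for e in envs]
        fitted = fit_jarvis_gsmax(envs, gs_obs, base,
                                  free=("gs_max", "k_vpd"))
        assert fitted["gs_max"] == pytest.approx(0.40, rel=0.05)
        assert fitted["k_vpd"] == pytest.approx(0.5, rel=0.10)


class TestAciFitter:
    def test_recovers_generating_capacities(self):
        p = PhotoParams(Rd=1.0)
        vc_true, jm_true = 80.0, 140.0
        ci = np.linspace(50, 1200, 24)
        kco = p.Kc * (1 + p.O2 / p.Ko)
        ac = vc_true * (ci - p.gamma_star) / (ci + kco)
        aj = jm_true * (ci - p.gamma_star) / (4 * (ci + 2 * p.gamma_star))
        a = np.minimum(ac, aj) - p.Rd
        vc, jm, sse = fit_vcmax_jmax(ci, a, p)
        assert vc == pytest.approx(vc_true, rel=0.02)
        assert jm == pytest.approx(jm_true, rel=0.02)
        assert sse < 1e-3
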