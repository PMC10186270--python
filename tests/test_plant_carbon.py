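import numpy as np
import pytest

from tgfs.plant_carbon import (LeafPools, OrganPool, PhloemSinks,
                               leaf_balance_step, leaf_geometry,
                               maintenance_growth_respiration,
                               organ_balance_step, phloem_loading,
                               sink_uptake, solve_phloem_generic,
                               solve_phloem_sucrose, structural_growth_rate)


class TestStructuralGrowth:
    def test_no_reserve_no_growth(self):
        assert structural_growth_rate(LeafPools(10.0, 0.0), 0.002) == 0.0

    def test_hand_value(self):
        assert structural_growth_rate(LeafPools(10.0, 10.0), 0.002) == pytest.approx(0.01)

    def test_bounded_by_relative_maximum(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cs, cn = rng.uniform(0, 20, 2)
            rate = structural_growth_rate(LeafPools(cs, cn), 0.002)
            assert 0.0 <= rate <= cs * 0.002 + 1e-15

    def test_empty_plant_guard(self):
        assert structural_growth_rate(LeafPools(0.0, 0.0), 0.002) == 0.0


class TestLeafGeometry:
    def test_no_structure_no_area(self):
        la, _ = leaf_geometry(LeafPools(0.0, 1.0), 0.03, 0.36)
        assert la == 0.0

    def test_carbon_fraction_to_dry_weight(self):
        # 0.36 g C at 0.36 g C per g DW is exactly 1 g of leaf
        _, dw = leaf_geometry(LeafPools(0.30, 0.06), 0.03, 0.36)
        assert dw == pytest.approx(1.0)

    def test_area_proportional_to_structure(self):
        la, _ = leaf_geometry(LeafPools(2.0, 0.5), 0.1, 0.36)
        assert la == pytest.approx(0.2)


class TestRespiration:
    def test_reference_temperature_unit_q10(self):
        r = maintenance_growth_respiration(50.0, 20.0, 0.0, 1e-4, 0.3, 2.0)
        assert r == pytest.approx(1e-4 * 50.0)

    def test_q10_doubles_per_ten_degrees(self):
        r20 = maintenance_growth_respiration(50.0, 20.0, 0.0, 1e-4, 0.3, 2.0)
        r30 = maintenance_growth_respiration(50.0, 30.0, 0.0, 1e-4, 0.3, 2.0)
        assert r30 == pytest.approx(2 * r20)

    def test_hand_value_with_growth_term(self):
        r = maintenance_growth_respiration(50.0, 25.0, 0.01, 1e-4, 0.3, 2.0)
        assert r == pytest.approx(1e-4 * 50 * 2 ** 0.5 + 0.003, rel=1e-9)


class TestPhloemLoading:
    def test_empty_reserve_loads_nothing(self):
        assert phloem_loading(LeafPools(5.0, 0.0), 0.2, 0.5, 0.2) == 0.0

    def test_saturates_at_capacity(self):
        # r >> K_mleaf
        load = phloem_loading(LeafPools(0.001, 10.0), 0.2, 0.5, 0.001)
        assert load == pytest.approx(0.2 * 0.5, rel=2e-3)
        assert load < 0.2 * 0.5

    def test_half_saturation(self):
        # r = K_mleaf = 0.5 when C_ns = C_str
        load = phloem_loading(LeafPools(3.0, 3.0), 0.2, 0.5, 0.5)
        assert load == pytest.approx(0.2 * 0.5 / 2)


class TestSinkUptake:
    def test_no_sucrose_no_uptake(self):
        assert sink_uptake(5.0, 100.0, 0.0, 0.1, 0.002, 900.0) == 0.0

    def test_logistic_midpoint(self):
        u = sink_uptake(5.0, 900.0, 0.02, 0.1, 0.002, 900.0)
        assert u == pytest.approx(5.0 * 0.05 * 0.02)

    def test_attenuates_to_zero(self):
        assert sink_uptake(5.0, 1e7, 0.02, 0.1, 0.002, 900.0) == 0.0

    def test_nonincreasing_in_time(self):
        us = [sink_uptake(5.0, t, 0.02, 0.1, 0.002, 900.0)
              for t in (0, 400, 900, 1500, 3000)]
        assert all(b <= a for a, b in zip(us, us[1:]))


class TestOrganBalance:
    def test_steady_state(self):
        pool = OrganPool("stem", 3.6)
        dw = 3.6 / 0.45
        maint = 1e-4 * dw  # at 20 degC
        dC, _ = organ_balance_step(pool, maint, 20.0, 1e-4, 0.3, 2.0, 0.45)
        assert dC == pytest.approx(0.0, abs=1e-15)

    def test_dry_weight_conversion(self):
        _, dw = organ_balance_step(OrganPool("root", 3.6), 0.0, 20.0,
                                   1e-4, 0.3, 2.0, 0.45)
        assert dw == pytest.approx(8.0)

    def test_no_uptake_decays_by_maintenance_only(self):
        pool = OrganPool("stem", 4.5)
        dC, dw = organ_balance_step(pool, 0.0, 20.0, 1e-4, 0.0, 2.0, 0.45)
        assert dC == pytest.approx(-1e-4 * dw)

    def test_growth_respiration_consistency(self):
        # with dC = (u - maint)/(1 + qg), resp = u - dC must equal
        # maint + qg*dC (the implicit formulation)
        pool = OrganPool("stem", 10.0)
        u, qm, qg = 0.05, 1e-4, 0.3
        dC, dw = organ_balance_step(pool, u, 25.0, qm, qg, 2.0, 0.42)
        maint = qm * dw * 2.0 ** 0.5
        assert u - dC == pytest.approx(maint + qg * dC, rel=1e-12)


class TestLeafBalance:
    def test_pure_source(self):
        assert leaf_balance_step(0.5, 0.0, 0.0, 0.0) == 0.5

    def test_night_drawdown_negative(self):
        assert leaf_balance_step(0.0, 0.1, 0.02, 0.05) < 0

    def test_hand_arithmetic(self):
        assert leaf_balance_step(0.5, 0.2, 0.05, 0.1) == pytest.approx(0.15)


class TestPhloemClosure:
    def test_no_supply_no_concentration(self):
        cp = solve_phloem_sucrose(0.0, PhloemSinks(a_lin=1.0))
        assert cp == 0.0

    def test_linear_sinks_closed_form(self):
        # stem + root only: Cp = loading / (a_stem + a_root)
        a = 2.5 + 1.5
        cp = solve_phloem_sucrose(0.12, PhloemSinks(a_lin=a))
        assert cp == pytest.approx(0.12 / a, rel=1e-14)

    def test_residual_contract_with_saturable_term(self):
        sinks = PhloemSinks(a_lin=1.2, beta=0.8, Km=0.08, gamma=0.01)
        loading = 0.3
        cp = solve_phloem_sucrose(loading, sinks, Cp_max=10.0)
        resid = (sinks.a_lin * cp + sinks.beta * cp / (sinks.Km + cp)
                 - sinks.gamma - loading)
        assert abs(resid) <= 1e-9 * max(1.0, loading)

    def test_monotone_in_loading(self):
        sinks = PhloemSinks(a_lin=1.2, beta=0.8, Km=0.08)
        cps = [solve_phloem_sucrose(l, sinks, Cp_max=10.0)
               for l in (0.01, 0.05, 0.1, 0.2)]
        assert all(b > a for a, b in zip(cps, cps[1:]))

    def test_generic_solver_agrees_with_closed_form(self):
        sinks = PhloemSinks(a_lin=1.2, beta=0.8, Km=0.08, gamma=0.02)

        def uptake(cp):
            return sinks.a_lin * cp + sinks.beta * cp / (sinks.Km + cp) - sinks.gamma

        for loading in (0.02, 0.1, 0.4):
            closed = solve_phloem_sucrose(loading, sinks, Cp_max=10.0)
            generic = solve_phloem_generic(loading, uptake, Cp_max=10.0)
            assert generic == pytest.approx(closed, abs=1e-10)

    def test_saturated_sinks_raise(self):
        with pytest.raises(ArithmeticError):
            solve_phloem_sucrose(1.0, PhloemSinks(a_lin=0.0, beta=0.5, Km=0.1))
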