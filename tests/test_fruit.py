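import dataclasses

import pytest

from tgfs.fruit import (FruitState, fruit_quality, fruit_surface_area,
                        fruit_sugar_uptake, fruit_water_flux,
                        fruit_water_relations, osmotic_potential,
                        starch_degradation_coefficient,
                        starch_synthesis_coefficient, sugar_metabolism_step,
                        wall_extensibility)
from tgfs.params import FruitParams


@pytest.fixture
def fp():
    return FruitParams()


@pytest.fixture
def young_fruit():
    return FruitState(W=10.0, C_suc=0.02, C_hex=0.08, C_sta=0.03, C_other=0.3)


class TestSurfaceArea:
    def test_massless_fruit(self):
        assert fruit_surface_area(0.0, 3.65, 0.73) == 0.0

    def test_hand_value(self):
        assert fruit_surface_area(100.0, 3.65, 0.73) == pytest.approx(105.0, abs=0.5)

    def test_power_law_scaling(self):
        a1 = fruit_surface_area(50.0, 3.65, 0.73)
        a2 = fruit_surface_area(100.0, 3.65, 0.73)
        assert a2 / a1 == pytest.approx(2 ** 0.73, rel=1e-12)


class TestWaterRelations:
    def test_no_gradient_no_influx(self, fp, young_fruit, make_env):
        env = make_env(RH=100.0)  # no transpiration demand
        rel = fruit_water_relations(0.0, young_fruit, env, fp, t=100.0)
        # pick psi_stem equal to the solved psi_fruit: flux must vanish
        rel2 = fruit_water_relations(rel.psi_fruit, young_fruit, env, fp, t=100.0)
        if not rel2.expanding:
            assert rel2.influx == pytest.approx(0.0, abs=1e-9)

    def test_no_vpd_no_fruit_transpiration(self, fp, young_fruit, make_env):
        env = make_env(RH=100.0)
        _, transp = fruit_water_flux(-0.05, young_fruit, env, fp, t=100.0)
        assert transp == 0.0

    def test_influx_monotone_in_stem_potential(self, fp, young_fruit, make_env):
        env = make_env()
        fluxes = [fruit_water_flux(ps, young_fruit, env, fp, t=100.0)[0]
                  for ps in (-1.2, -0.8, -0.4, -0.1)]
        assert all(b >= a for a, b in zip(fluxes, fluxes[1:]))

    def test_turgor_nonnegative_and_expansion_above_yield(self, fp, young_fruit, make_env):
        rel = fruit_water_relations(-0.05, young_fruit, make_env(), fp, t=100.0)
        assert rel.P >= 0.0
        if rel.expanding:
            assert rel.P > fp.Y

    def test_extensibility_declines_with_floor(self, fp):
        assert wall_extensibility(0.0, fp) == fp.phi0
        assert wall_extensibility(fp.tau_s, fp) == fp.phi0
        late = wall_extensibility(fp.tau_s + 5000.0, fp)
        assert fp.phi_min <= late < fp.phi0
        assert wall_extensibility(1e6, fp) == fp.phi_min

    def test_osmotic_potential_increases_with_sugar(self, fp, young_fruit):
        sweeter = dataclasses.replace(young_fruit, C_hex=0.3)
        assert (osmotic_potential(sweeter, 25.0, fp)
                > osmotic_potential(young_fruit, 25.0, fp))


class TestSugarUptake:
    def test_no_sucrose_anywhere_no_uptake(self, fp, make_env):
        fruit = FruitState(W=10.0, C_suc=0.0, C_hex=0.0, C_sta=0.0, C_other=0.3)
        assert fruit_sugar_uptake(0.0, 0.0, fruit, 100.0, fp) == 0.0

    def test_active_transport_logistic_midpoint(self, fp, young_fruit):
        fp0 = dataclasses.replace(fp, ps=0.0)
        early = fruit_sugar_uptake(0.05, 0.0, young_fruit, 0.0, fp0)
        mid = fruit_sugar_uptake(0.05, 0.0, young_fruit, fp0.t_star, fp0)
        # the logistic gate is ~1 early and exactly 1/2 at t*
        assert mid / early == pytest.approx(0.5, rel=2e-3)

    def test_active_transport_shuts_down_late(self, fp, young_fruit):
        fp0 = dataclasses.replace(fp, ps=0.0)
        late = fruit_sugar_uptake(0.05, 0.0, young_fruit, 1e6, fp0)
        assert late == 0.0

    def test_mass_flow_advects_at_phloem_concentration(self, fp):
        fruit = FruitState(W=10.0, C_suc=0.0, C_hex=0.0, C_sta=0.0, C_other=0.3)
        fp0 = dataclasses.replace(fp, ps=0.0, vm=0.0)
        cp = 0.04
        us = fruit_sugar_uptake(cp, 2.0, fruit, 100.0, fp0)
        assert us == pytest.approx(2.0 * cp / fp0.c_suc)


class TestSugarMetabolism:
    def test_all_rates_zero_means_static_pools(self, fp, young_fruit):
        frozen = dataclasses.replace(fp, k_sh=0.0, k_oth=0.0, k5=0.0,
                                     k5d=0.0, q_mfruit=0.0, q_gfruit=0.0)
        derivs = sugar_metabolism_step(young_fruit, 0.0, 20.0, 25.0, frozen)
        assert all(d == 0.0 for d in derivs)

    def test_carbon_conservation_by_construction(self, fp, young_fruit):
        ds, dh, dsta, doth, mresp = sugar_metabolism_step(
            young_fruit, 0.05, 20.0, 25.0, fp)
        assert ds + dh + dsta + doth == pytest.approx(
            0.05 * fp.c_suc - mresp, rel=1e-12)

    def test_starch_synthesis_peaks_early_degradation_late(self, fp):
        ks = [starch_synthesis_coefficient(d, fp) for d in (0, 20, 40, 60, 90)]
        kd = [starch_degradation_coefficient(d, fp) for d in (0, 20, 40, 60, 90)]
        assert all(b <= a for a, b in zip(ks, ks[1:]))
        assert all(b >= a for a, b in zip(kd, kd[1:]))
        assert ks[0] == pytest.approx(fp.k5, rel=0.01)
        assert kd[-1] == pytest.approx(fp.k5d, rel=0.01)


class TestFruitQuality:
    def test_hand_example(self, fp):
        # 100 g fruit carrying 3 g of soluble sugars: SSc = 3.0 per 100 g FW
        m_suc, m_hex = 1.0, 2.0
        c_suc = m_suc * fp.c_suc
        c_hex = m_hex * fp.c_hex
        dw_target = 5.0
        c_other = dw_target * fp.c_fruit - c_suc - c_hex
        fruit = FruitState(W=95.0, C_suc=c_suc, C_hex=c_hex, C_sta=0.0,
                           C_other=c_other)
        fw, dw, ssc, stac = fruit_quality(fruit, fp)
        assert fw == pytest.approx(100.0)
        assert dw == pytest.approx(5.0)
        assert ssc == pytest.approx(3.0)
        assert stac == 0.0

    def test_empty_fruit_flagged_zeros(self, fp):
        fruit = FruitState(W=0.0, C_suc=0.0, C_hex=0.0, C_sta=0.0, C_other=0.0)
        assert fruit_quality(fruit, fp) == (0.0, 0.0, 0.0, 0.0)

    def test_sugars_are_part_of_dry_weight(self, fp, young_fruit):
        fw, dw, ssc, stac = fruit_quality(young_fruit, fp)
        # soluble + starch mass cannot exceed total dry matter
        assert ssc + stac <= 100.0 * dw / fw / min(fp.c_suc, fp.c_hex, fp.c_sta) * fp.c_fruit
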