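"""Representative-truss fruit biophysics and sugar metabolism.

The fruit compartment is a single "big truss": ``Fn`` identical fruits per
plant, each carrying a water mass W and four carbon pools (sucrose, hexose,
starch, structural/other).  Water enters along the stem-to-fruit water
potential gradient through a composite xylem+phloem conductivity and leaves
by surface transpiration; irreversible expansion follows Lockhart kinetics
with an age-declining wall extensibility.  Sucrose enters by active
(Michaelis-Menten, developmentally gated) transport, phloem mass flow and
passive diffusion; inside the fruit it is inverted to hexose, polymerised
to starch (early synthesis, later degradation) and incorporated into
structural matter, with maintenance and growth respiration closing the
carbon budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .drivers import EnvForcing
from .params import FruitParams

__all__ = [
    "FruitState",
    "WaterRelations",
    "fruit_surface_area",
    "wall_extensibility",
    "osmotic_potential",
    "fruit_water_relations",
    "fruit_water_flux",
    "fruit_sugar_uptake",
    "starch_synthesis_coefficient",
    "starch_degradation_coefficient",
    "sugar_metabolism_step",
    "fruit_quality",
]

#: molar masses, g mol-1
M_SUCROSE = 342.30
M_HEXOSE = 180.16
#: gas constant in MPa L mol-1 K-1
R_GAS = 8.3145e-3


@dataclass(slots=True)
class FruitState:
    """Per-fruit water mass and carbon sub-pools (g and g C)."""

    W: float          # water mass, g
    C_suc: float      # sucrose carbon, g C
    C_hex: float      # hexose carbon, g C
    C_sta: float      # starch carbon, g C
    C_other: float    # structural / acids / other carbon, g C

    def __post_init__(self) -> None:
        if min(self.W, self.C_suc, self.C_hex, self.C_sta, self.C_other) < 0:
            raise ValueError("fruit state components must be >= 0")

    @property
    def C_total(self) -> float:
        return self.C_suc + self.C_hex + self.C_sta + self.C_other


def fruit_surface_area(FW: float, lam: float, n: float) -> float:
    """Fruit surface area A = lam * FW**n (cm2), increasing in fresh weight."""
    if FW < 0:
        raise ValueError("FW must be >= 0")
    return lam * FW ** n if FW > 0 else 0.0


def wall_extensibility(t: float, p: FruitParams) -> float:
    """Cell-wall extensibility phi(t) (MPa-1 h-1): constant early, then an
    exponential decline after ``tau_s`` hours, floored at ``phi_min``."""
    if t <= p.tau_s:
        return p.phi0
    return max(p.phi_min, p.phi0 * math.exp(-p.k_phi * (t - p.tau_s)))


def _sugar_masses(fruit: FruitState, p: FruitParams) -> tuple[float, float, float]:
    """(sucrose, hexose, starch) masses in g from the carbon pools."""
    return fruit.C_suc / p.c_suc, fruit.C_hex / p.c_hex, fruit.C_sta / p.c_sta


def osmotic_potential(fruit: FruitState, Ta: float, p: FruitParams) -> float:
    """Fruit sap osmotic pressure pi (MPa, > 0) via van 't Hoff on the
    soluble sugars plus a fixed offset for acids/ions not book-kept."""
    if fruit.W <= 0:
        return p.pi_other
    m_suc, m_hex, _ = _sugar_masses(fruit, p)
    mol = m_suc / M_SUCROSE + m_hex / M_HEXOSE       # mol solute
    conc = mol / (fruit.W / 1000.0)                  # mol L-1 (sap ~ water)
    return R_GAS * (Ta + 273.15) * conc + p.pi_other


class WaterRelations(NamedTuple):
    influx: float        # g h-1, net water inflow through xylem + phloem
    transpiration: float  # g h-1, fruit surface transpiration
    psi_fruit: float     # MPa
    P: float             # MPa, turgor
    pi: float            # MPa, osmotic pressure
    area: float          # cm2
    expanding: bool


def fruit_water_relations(psi_stem: float, fruit: FruitState,
                          env: EnvForcing, p: FruitParams,
                          t: float) -> WaterRelations:
    """Quasi-steady turgor closure and the resulting water fluxes.

    Turgor P solves the Lockhart balance: vascular influx minus surface
    transpiration equals the irreversible expansion W * phi * (P - Y) when
    P exceeds the yield threshold Y.  Below threshold there is no
    expansion and P floats to the value that zeroes the net water flux,
    clipped to [0, Y] (a flaccid fruit at P = 0 may lose water).
    """
    fw, dw, _, _ = fruit_quality(fruit, p)
    area = fruit_surface_area(fw, p.lam, p.n_allom)
    pi = osmotic_potential(fruit, env.Ta, p)
    transp = area * p.rho_transp * env.VPD
    alp = area * p.Lp
    phi = wall_extensibility(t, p)
    wphi = fruit.W * phi
    if alp + wphi > 0.0:
        p_grow = (alp * (psi_stem + pi) - transp + wphi * p.Y) / (alp + wphi)
    else:
        p_grow = 0.0
    if p_grow > p.Y:
        P = p_grow
        expanding = True
    else:
        P = (alp * (psi_stem + pi) - transp) / alp if alp > 0 else 0.0
        P = min(max(P, 0.0), p.Y)
        expanding = False
    psi_fruit = P - pi
    influx = alp * (psi_stem - psi_fruit)
    return WaterRelations(influx, transp, psi_fruit, P, pi, area, expanding)


def fruit_water_flux(psi_stem: float, fruit: FruitState, env: EnvForcing,
                     p: FruitParams, t: float = 0.0) -> tuple[float, float]:
    """(vascular influx, surface transpiration) in g h-1; the influx may be
    negative (backflow towards the stem under severe water stress)."""
    rel = fruit_water_relations(psi_stem, fruit, env, p, t)
    return rel.influx, rel.transpiration


def fruit_sugar_uptake(Cp: float, phloem_influx: float, fruit: FruitState,
                       t: float, p: FruitParams) -> float:
    """Sucrose import rate U_s (g sucrose h-1) from the phloem.

    Three routes: active transport vm(t) * DW * Cp/(Km + Cp) with a logistic
    developmental shutdown vm(t) = vm / (1 + exp((t - t*)/tau)); mass flow
    advected by the phloem water influx (at phloem concentration on the way
    in, at fruit sap concentration on the way out); passive diffusion down
    the sap concentration difference.  Cp is phloem sucrose as g C per g
    sap; mass-basis concentrations divide by the sucrose carbon fraction.
    """
    if Cp < 0:
        raise ValueError("Cp must be >= 0")
    _, dw, _, _ = fruit_quality(fruit, p)
    fw = fruit.W + dw
    area = fruit_surface_area(fw, p.lam, p.n_allom)
    m_suc, m_hex, _ = _sugar_masses(fruit, p)
    s_fruit = (m_suc + m_hex) / fruit.W if fruit.W > 0 else 0.0
    cp_mass = Cp / p.c_suc
    z = (t - p.t_star) / p.tau
    vm_t = 0.0 if z > 700.0 else p.vm / (1.0 + math.exp(z))
    active = vm_t * dw * Cp / (p.Km_up + Cp)
    if phloem_influx >= 0.0:
        mass_flow = phloem_influx * cp_mass
    else:
        mass_flow = phloem_influx * s_fruit
    diffusion = p.ps * area * (cp_mass - s_fruit)
    return active + mass_flow + diffusion


def starch_synthesis_coefficient(daa: float, p: FruitParams) -> float:
    """k5(daa) = k5 * k5m0 / (k5m0 + exp(u5m (daa - tau5m))): near-maximal
    early in development, declining logistically afterwards (h-1)."""
    z = p.u5m * (daa - p.tau5m)
    if z > 700.0:
        return 0.0
    return p.k5 * p.k5m0 / (p.k5m0 + math.exp(z))


def starch_degradation_coefficient(daa: float, p: FruitParams) -> float:
    """Starch breakdown coefficient (h-1), activating as synthesis wanes:
    k5d * [1 - k5m0 / (k5m0 + exp(u5m (daa - tau5m)))]."""
    z = p.u5m * (daa - p.tau5m)
    if z > 700.0:
        return p.k5d
    return p.k5d * (1.0 - p.k5m0 / (p.k5m0 + math.exp(z)))


def sugar_metabolism_step(fruit: FruitState, U_s: float, daa: float,
                          Ta: float, p: FruitParams
                          ) -> tuple[float, float, float, float, float]:
    """Carbon-pool derivatives (dC_suc, dC_hex, dC_sta, dC_other, Mresp).

    Imported sucrose carbon enters the sucrose pool and is inverted to
    hexose (first order, k_sh); hexose feeds starch synthesis (early-peaked
    coefficient), structural growth (k_oth) and respiration; starch is
    remobilised back to hexose late in development.  The derivatives sum to
    U_s * c_suc - Mresp by construction (fruit carbon conservation).
    Maintenance respiration carries a saturable hexose-availability factor
    so the pool cannot be driven negative.
    """
    usc = U_s * p.c_suc
    k5t = starch_synthesis_coefficient(daa, p)
    kdeg = starch_degradation_coefficient(daa, p)
    dC_other = p.k_oth * fruit.C_hex
    dw = fruit.C_total / p.c_fruit
    avail = fruit.C_hex / (fruit.C_hex + p.K_sub) if fruit.C_hex > 0 else 0.0
    maint = p.q_mfruit * dw * p.Q10 ** ((Ta - 20.0) / 10.0) * avail
    mresp = maint + p.q_gfruit * dC_other
    dC_suc = usc - p.k_sh * fruit.C_suc
    dC_sta = k5t * fruit.C_hex - kdeg * fruit.C_sta
    dC_hex = (p.k_sh * fruit.C_suc - k5t * fruit.C_hex + kdeg * fruit.C_sta
              - dC_other - mresp)
    return dC_suc, dC_hex, dC_sta, dC_other, mresp


def fruit_quality(fruit: FruitState, p: FruitParams
                  ) -> tuple[float, float, float, float]:
    """(FW, DW, SSc, Stac): fresh weight, dry weight (g) and soluble sugar
    and starch concentrations (g per 100 g FW).  A massless fruit returns
    flagged zeros."""
    dw = fruit.C_total / p.c_fruit
    fw = fruit.W + dw
    if fw <= 0.0:
        return 0.0, 0.0, 0.0, 0.0
    m_suc, m_hex, m_sta = _sugar_masses(fruit, p)
    ssc = 100.0 * (m_suc + m_hex) / fw
    stac = 100.0 * m_sta / fw
    return fw, dw, ssc, stac
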