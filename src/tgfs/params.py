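"""Parameter containers for the whole-plant tomato simulator.

Every constant of the conductance, photosynthesis, water-transport, carbon
allocation and fruit modules lives in one of the dataclasses below, grouped
the way the parameter YAML file is grouped (``stomatal:``, ``photosynthesis:``,
``water:``, ``carbon:``, ``fruit:`` blocks).  All defaults are package choices
calibrated to produce a realistic indeterminate greenhouse tomato; they are
meant to be replaced by fitted values for any real dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Callable

import yaml

__all__ = [
    "StomatalParams",
    "PhotoParams",
    "WaterParams",
    "CarbonParams",
    "FruitParams",
    "ParameterSet",
    "InitialState",
    "default_parameters",
    "load_params",
    "save_params",
    "load_initial_state",
]


@dataclass
class StomatalParams:
    """Multiplicative (Jarvis-type) stomatal conductance parameters.

    ``gs_max`` is the unstressed maximum conductance (mol H2O m-2 s-1); the
    remaining fields shape the six [0, 1] environmental reduction functions
    for net radiation, air temperature, VPD, soil water, soil mineral N and
    atmospheric CO2.  Alternative functional forms can be injected through
    ``forms`` (mapping factor name -> callable) without touching the code.
    """

    gs_max: float = 0.32          # mol H2O m-2 s-1
    k_rn: float = 0.15            # MJ m-2 h-1, half-saturation of f(Rn')
    T_opt: float = 26.0           # degC, optimum of f(Ta)
    T_width: float = 18.0         # degC, half-width of the quadratic f(Ta)
    k_vpd: float = 0.35           # kPa-1, hyperbolic decline of f(VPD)
    theta_w: float = 0.10         # cm3 cm-3, wilting point (f(theta)=0)
    theta_c: float = 0.30         # cm3 cm-3, critical theta (f(theta)=1)
    N_opt: float = 120.0          # mg kg-1, optimum soil mineral N
    N_width: float = 150.0        # mg kg-1, half-width of the biphasic f(N)
    co2_ref: float = 400.0        # umol mol-1, reference CO2 (f=1)
    s_co2: float = 0.30           # log-sensitivity of f(CO2)
    forms: dict[str, Callable[..., float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gs_max <= 0:
            raise ValueError("gs_max must be > 0")
        if not self.theta_w < self.theta_c:
            raise ValueError("theta_w must be < theta_c")


@dataclass
class PhotoParams:
    """Farquhar (C3) photosynthesis parameters with age-declining capacities.

    Vcmax and Jmax decline linearly with fruit age (days after anthesis),
    clipped at zero: Vcmax(daa) = max(0, vcmax25 + vcmax_slope * daa).
    Michaelis constants are held at their 25 degC values (leaf temperature is
    taken equal to air temperature and no kinetic temperature response is
    applied; see the methods note).
    """

    vcmax25: float = 100.0        # umol m-2 s-1 at daa = 0
    vcmax_slope: float = -0.55    # umol m-2 s-1 day-1 (negative: ageing)
    jmax25: float = 180.0         # umol m-2 s-1 at daa = 0
    jmax_slope: float = -0.95     # umol m-2 s-1 day-1
    Rd: float = 0.0               # umol m-2 s-1 leaf dark respiration
    gamma_star: float = 42.75     # umol mol-1 CO2 compensation point
    Kc: float = 404.9             # umol mol-1
    Ko: float = 278.4             # mmol mol-1
    O2: float = 210.0             # mmol mol-1, oxygen mole fraction
    alpha: float = 0.24           # mol e- (mol photon)-1 quantum yield
    theta_J: float = 0.7          # curvature of the light response of J
    par_factor: float = 635.0     # umol photon m-2 s-1 per (MJ m-2 h-1)

    def __post_init__(self) -> None:
        if self.gamma_star <= 0:
            raise ValueError("gamma_star must be > 0")

    def vcmax(self, daa: float) -> float:
        return max(0.0, self.vcmax25 + self.vcmax_slope * daa)

    def jmax(self, daa: float) -> float:
        return max(0.0, self.jmax25 + self.jmax_slope * daa)


@dataclass
class WaterParams:
    """Soil-to-stem water transport parameters.

    ``Rp`` (MPa h g-1) is the lumped hydraulic resistance between the soil
    and the stem base; its default is a placeholder of realistic magnitude
    for a pot-grown tomato, not a fitted value.  The soil retention curve is
    pluggable: ``van_genuchten`` (default), ``campbell`` or ``table``.
    """

    Rp: float = 0.002             # MPa h g-1
    retention: str = "van_genuchten"
    theta_sat: float = 0.43       # cm3 cm-3
    theta_res: float = 0.078      # cm3 cm-3
    vg_alpha: float = 0.036       # cm-1 (van Genuchten)
    vg_n: float = 1.56            # shape (van Genuchten)
    cb_psi_e: float = -0.0015     # MPa air-entry (Campbell)
    cb_b: float = 5.0             # shape (Campbell)
    table_theta: list[float] | None = None
    table_psi: list[float] | None = None
    psi_min: float = -3.0         # MPa floor below theta_res
    P_atm: float = 101.325        # kPa

    def __post_init__(self) -> None:
        if self.Rp <= 0:
            raise ValueError("Rp must be > 0")
        if not self.theta_res < self.theta_sat:
            raise ValueError("theta_res must be < theta_sat")


@dataclass
class CarbonParams:
    """Leaf, stem and root carbon pool parameters (vegetative side)."""

    K_ml: float = 0.0065          # h-1, max relative leaf structural growth
    SLAs: float = 0.028           # m2 (g C structural)-1
    V_maxleaf: float = 0.85       # g C m-2 h-1, max phloem loading per LA
    K_mleaf: float = 0.25         # dimensionless C_ns fraction
    c_leaf: float = 0.36          # g C (g DW)-1, tomato leaf
    c_stem: float = 0.42          # g C (g DW)-1
    c_root: float = 0.42          # g C (g DW)-1
    q_mleaf: float = 2.0e-4       # g C (g DW)-1 h-1 maintenance at 20 degC
    q_mstem: float = 1.0e-4
    q_mroot: float = 1.5e-4
    q_gleaf: float = 0.28         # g C respired (g C grown)-1
    q_gstem: float = 0.28
    q_groot: float = 0.28
    Q10: float = 2.0
    K_pstem: float = 0.28         # h-1 (g C g sap-1)-1, stem sink rate coeff
    A_pstem: float = 0.002        # h-1, attenuation of stem sink activity
    B_pstem: float = 1100.0        # h, timing of stem sink attenuation
    K_proot: float = 0.25
    A_proot: float = 0.002
    B_proot: float = 900.0
    Cp_max: float = 0.25          # g C (g sap)-1, solver bracket cap
    K_sub: float = 0.002          # g C, substrate limitation of maintenance


@dataclass
class FruitParams:
    """Representative-truss ("big truss") fruit biophysics and sugar kinetics.

    Carbon is book-kept as g C per fruit in four pools (sucrose, hexose,
    starch, structural/other); sugar masses are recovered through the
    stoichiometric carbon fractions ``c_suc``/``c_hex``/``c_sta``.
    """

    Fn: float = 12.0              # fruits per plant (fixed; no abortion)
    # sucrose import
    vm: float = 0.035             # g sucrose (g DW)-1 h-1, max active uptake
    t_star: float = 1700.0         # h, midpoint of active-uptake decline
    tau: float = 150.0            # h, decline time constant
    Km_up: float = 0.08           # g C (g sap)-1, active uptake Km vs Cp
    axp: float = 1.0              # xylem:phloem water influx ratio
    ps: float = 8.0e-4            # g cm-2 h-1, sugar diffusion coefficient
    # water relations / expansion
    Lp: float = 0.035             # g h-1 cm-2 MPa-1 composite conductivity
    lam: float = 3.65             # surface allometry A = lam * FW**n (cm2)
    n_allom: float = 0.73
    phi0: float = 0.012           # MPa-1 h-1 initial wall extensibility
    k_phi: float = 0.0040         # h-1 extensibility decline
    tau_s: float = 1100.0          # h, extensibility decline onset
    phi_min: float = 1.0e-5       # MPa-1 h-1 extensibility floor
    Y: float = 0.25               # MPa yield-threshold turgor
    rho_transp: float = 6.0e-4    # g cm-2 h-1 kPa-1 fruit surface transpiration
    pi_other: float = 0.30        # MPa osmotic contribution of non-sugar solutes
    # carbon stoichiometry
    c_suc: float = 0.4211         # g C (g sucrose)-1
    c_hex: float = 0.4001         # g C (g hexose)-1
    c_sta: float = 0.4444         # g C (g starch)-1
    c_fruit: float = 0.44         # g C (g fruit DW)-1
    # sugar metabolism
    k_sh: float = 0.050           # h-1 sucrose -> hexose
    k_oth: float = 0.0015         # h-1 hexose -> structural/other
    k5: float = 0.004             # h-1 max starch synthesis coefficient
    k5m0: float = 30.0            # dimensionless, synthesis schedule scale
    u5m: float = 0.25             # day-1, synthesis decline steepness
    tau5m: float = 25.0           # daa, synthesis decline midpoint
    k5d: float = 0.002            # h-1 max starch degradation coefficient
    # respiration
    q_mfruit: float = 1.5e-4      # g C (g DW)-1 h-1
    q_gfruit: float = 0.08        # g C (g C structural)-1
    Q10: float = 2.0
    K_sub: float = 5.0e-4         # g C, substrate limitation of maintenance


@dataclass
class ParameterSet:
    """Aggregate of all module parameter blocks."""

    stomatal: StomatalParams = field(default_factory=StomatalParams)
    photosynthesis: PhotoParams = field(default_factory=PhotoParams)
    water: WaterParams = field(default_factory=WaterParams)
    carbon: CarbonParams = field(default_factory=CarbonParams)
    fruit: FruitParams = field(default_factory=FruitParams)

    def replace(self, **named: dict[str, Any]) -> "ParameterSet":
        """Return a deep copy with ``block.field`` overrides.

        ``named`` maps dotted names (``"carbon.K_pstem"``) to new values.
        """
        blocks = {
            name: dataclasses.replace(getattr(self, name))
            for name in ("stomatal", "photosynthesis", "water", "carbon", "fruit")
        }
        for dotted, value in named.items():
            block, _, fieldname = dotted.partition(".")
            if not fieldname or not hasattr(blocks.get(block, None), fieldname):
                raise KeyError(f"unknown parameter {dotted!r}")
            setattr(blocks[block], fieldname, value)
        return ParameterSet(**blocks)


@dataclass
class InitialState:
    """Initial plant and fruit state, in the observable units a grower
    measures (organ dry weights, fruit FW/DW, sugar and starch
    concentrations); converted to carbon pools inside ``simulate``."""

    DW_leaf: float = 8.0          # g
    frac_Cstr: float = 0.80       # structural fraction of leaf carbon
    DW_stem: float = 5.0          # g
    DW_root: float = 2.0          # g
    fruit_FW: float = 1.2         # g per fruit
    fruit_DW: float = 0.10        # g per fruit
    SSc: float = 1.5              # g soluble sugar / 100 g FW
    Stac: float = 0.5             # g starch / 100 g FW
    suc_frac: float = 0.30        # sucrose share of soluble sugar mass


# ---------------------------------------------------------------------------
# YAML round trip

_BLOCKS = {
    "stomatal": StomatalParams,
    "photosynthesis": PhotoParams,
    "water": WaterParams,
    "carbon": CarbonParams,
    "fruit": FruitParams,
}


def default_parameters() -> ParameterSet:
    return ParameterSet()


def _asdict_block(block: Any) -> dict[str, Any]:
    d = dataclasses.asdict(block)
    d.pop("forms", None)  # callables are code-injected, not serialisable
    return d


def save_params(params: ParameterSet, path: str) -> None:
    doc = {name: _asdict_block(getattr(params, name)) for name in _BLOCKS}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path: str) -> ParameterSet:
    """Load a parameter YAML; unspecified fields keep their defaults."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    kwargs = {}
    for name, cls in _BLOCKS.items():
        block = doc.get(name, {}) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(block) - valid
        if unknown:
            raise KeyError(f"unknown keys in {name!r} block: {sorted(unknown)}")
        kwargs[name] = cls(**block)
    return ParameterSet(**kwargs)


def load_initial_state(path: str) -> InitialState:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(InitialState)}
    unknown = set(doc) - valid
    if unknown:
        raise KeyError(f"unknown initial-state keys: {sorted(unknown)}")
    return InitialState(**doc)
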