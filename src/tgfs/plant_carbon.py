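"""Leaf, stem and root carbon dynamics and the phloem sucrose closure.

The leaf carries two carbon pools: structural carbon C_str (fixed in tissue,
sets leaf area through SLAs) and non-structural carbon C_ns (mobile reserve
that funds structural growth, respiration and phloem loading).  Stem and
root are single-pool sinks whose unloading rate is proportional to sink
size, a logistic developmental-stage activity and the phloem sap sucrose
concentration Cp.  Cp itself is not a state variable: at every instant it
is the root of the algebraic balance

    Loading_leaf = Uptake_stem(Cp) + Uptake_root(Cp) + Uptake_fruit(Cp)

which this module solves in closed form (the stem/root/mass-flow/diffusion
terms are linear in Cp and the active fruit transport term is
Michaelis-Menten, so the balance reduces to a quadratic) with a bracketed
numerical fallback for user-supplied uptake forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "LeafPools",
    "OrganPool",
    "PhloemSinks",
    "structural_growth_rate",
    "leaf_geometry",
    "maintenance_growth_respiration",
    "phloem_loading",
    "sink_uptake",
    "sink_activity",
    "organ_balance_step",
    "leaf_balance_step",
    "solve_phloem_sucrose",
    "solve_phloem_generic",
]


@dataclass(slots=True)
class LeafPools:
    """Leaf structural and non-structural carbon (g C)."""

    C_str: float
    C_ns: float

    def __post_init__(self) -> None:
        if self.C_str < 0 or self.C_ns < 0:
            raise ValueError("leaf carbon pools must be >= 0")

    @property
    def C_t(self) -> float:
        return self.C_str + self.C_ns


@dataclass(slots=True)
class OrganPool:
    """Stem or root carbon pool (g C)."""

    organ: str
    C_x: float

    def __post_init__(self) -> None:
        if self.organ not in ("stem", "root"):
            raise ValueError("organ must be 'stem' or 'root'")
        if self.C_x < 0:
            raise ValueError("organ carbon must be >= 0")


def structural_growth_rate(pools: LeafPools, K_ml: float) -> float:
    """Leaf structural growth dC_str/dt = C_str * K_ml * C_ns/(C_ns + C_str),
    g C h-1; zero when the leaf is empty or has no reserve."""
    ct = pools.C_str + pools.C_ns
    if ct <= 0.0:
        return 0.0
    return pools.C_str * K_ml * pools.C_ns / ct


def leaf_geometry(pools: LeafPools, SLAs: float, c_leaf: float) -> tuple[float, float]:
    """(LA, DW_leaf): leaf area LA = C_str * SLAs (m2) and dry weight
    DW_leaf = (C_ns + C_str) / c_leaf (g)."""
    return pools.C_str * SLAs, (pools.C_ns + pools.C_str) / c_leaf


def maintenance_growth_respiration(DW: float, Ta: float, dCstr_dt: float,
                                   q_m: float, q_g: float, Q10: float) -> float:
    """Organ respiration (g C h-1): temperature-sensitive maintenance plus
    growth respiration proportional to the structural increment."""
    if DW < 0:
        raise ValueError("DW must be >= 0")
    return q_m * DW * Q10 ** ((Ta - 20.0) / 10.0) + q_g * dCstr_dt


def phloem_loading(pools: LeafPools, LA: float, V_maxleaf: float,
                   K_mleaf: float) -> float:
    """Sucrose loading into the phloem (g C h-1): saturable in the leaf
    non-structural carbon fraction r = C_ns / (C_ns + C_str)."""
    ct = pools.C_str + pools.C_ns
    if ct <= 0.0:
        return 0.0
    r = pools.C_ns / ct
    return LA * V_maxleaf * r / (K_mleaf + r)


def sink_activity(t: float, K_p: float, A_p: float, B_p: float) -> float:
    """Developmental sink activity K_p / (1 + exp(A_p (t - B_p))), h-1 per
    unit Cp; declines with time since anthesis for A_p > 0."""
    z = A_p * (t - B_p)
    if z > 700.0:
        return 0.0
    return K_p / (1.0 + math.exp(z))


def sink_uptake(C_x: float, t: float, Cp: float, K_p: float, A_p: float,
                B_p: float) -> float:
    """Carbon unloading by a vegetative sink (g C h-1):
    Uptake = C_x * [K_p / (1 + exp(A_p (t - B_p)))] * Cp."""
    if C_x < 0 or Cp < 0:
        raise ValueError("C_x and Cp must be >= 0")
    return C_x * sink_activity(t, K_p, A_p, B_p) * Cp


def organ_balance_step(pool: OrganPool, uptake: float, Ta: float,
                       q_m: float, q_g: float, Q10: float,
                       c_x: float) -> tuple[float, float]:
    """(dC_x/dt, DW_x) for a stem or root pool.

    Respiration references the pool's own growth increment, which makes the
    balance implicit; resolving it explicitly gives

        dC_x/dt = (uptake - q_m DW Q10^((Ta-20)/10)) / (1 + q_g)

    when the numerator is positive (growth), and plain
    ``uptake - maintenance`` when the organ is shrinking (no growth
    respiration on a declining pool).
    """
    dw = pool.C_x / c_x
    maint = q_m * dw * Q10 ** ((Ta - 20.0) / 10.0)
    net = uptake - maint
    dC = net / (1.0 + q_g) if net > 0.0 else net
    return dC, dw


def leaf_balance_step(Pn_LA: float, loading: float, Mresp_leaf: float,
                      dCstr_dt: float) -> float:
    """Leaf reserve balance dC_ns/dt = Pn*LA - Loading - Mresp - dC_str/dt
    (g C h-1); all inputs must refer to the same instant."""
    return Pn_LA - loading - Mresp_leaf - dCstr_dt


# ---------------------------------------------------------------------------
# Phloem sucrose closure


@dataclass(slots=True)
class PhloemSinks:
    """Coefficients of the total phloem unloading rate as a function of Cp:

        S(Cp) = a_lin * Cp + beta * Cp / (Km + Cp) - gamma

    ``a_lin`` collects all terms linear in Cp (stem and root sinks, fruit
    phloem mass flow, fruit diffusive uptake); ``beta``/``Km`` is the
    saturable active fruit transport; ``gamma`` >= 0 collects Cp-independent
    sugar returns to the phloem (diffusion out of a sugar-rich fruit,
    backflow advection).
    """

    a_lin: float
    beta: float = 0.0
    Km: float = 1.0
    gamma: float = 0.0


def solve_phloem_sucrose(loading: float, sinks: PhloemSinks,
                         Cp_max: float = 0.25) -> float:
    """Solve Loading = S(Cp) for the phloem sap sucrose concentration.

    The balance is a quadratic in Cp, solved in closed form (numerically
    stable branch) and clipped at zero; residuals are at machine precision,
    far below the 1e-9 * max(1, loading) contract.  Raises if the sinks
    cannot absorb the load within [0, Cp_max] (pathological parameters).
    """
    if loading < 0:
        raise ValueError("loading must be >= 0")
    a, beta, km, gamma = sinks.a_lin, sinks.beta, sinks.Km, sinks.gamma
    R = loading + gamma
    if R <= 0.0:
        return 0.0
    if a <= 0.0:
        if beta <= R:
            raise ArithmeticError(
                f"phloem sinks saturate below the load (beta={beta:.3e} <= {R:.3e})")
        return R * km / (beta - R)
    # a*Cp^2 + (a*Km + beta - R)*Cp - R*Km = 0, positive root
    b = a * km + beta - R
    c = -R * km
    disc = b * b - 4.0 * a * c
    sq = math.sqrt(disc)
    if b >= 0.0:
        cp = (2.0 * -c) / (b + sq)      # avoids cancellation
    else:
        cp = (-b + sq) / (2.0 * a)
    cp = max(cp, 0.0)
    if cp > Cp_max:
        raise ArithmeticError(
            f"solved Cp={cp:.4f} exceeds Cp_max={Cp_max}; loading={loading:.4e}, "
            f"a_lin={a:.4e}, beta={beta:.4e}")
    return cp


def solve_phloem_generic(loading: float, uptake_fn, Cp_max: float = 0.25,
                         expansions: int = 6) -> float:
    """Bracketed numerical fallback for arbitrary monotone uptake forms.

    ``uptake_fn(Cp)`` must return the total unloading rate; the root of
    ``uptake_fn(Cp) - loading`` is bracketed on [0, Cp_max], expanding the
    upper bound a few times before giving up.
    """
    if loading < 0:
        raise ValueError("loading must be >= 0")

    def resid(cp: float) -> float:
        return uptake_fn(cp) - loading

    if resid(0.0) >= 0.0:
        return 0.0
    hi = Cp_max
    for _ in range(expansions):
        if resid(hi) >= 0.0:
            break
        hi *= 2.0
    else:
        raise ArithmeticError(
            f"no Cp in [0, {hi:.3g}] absorbs loading={loading:.4e}")
    cp = brentq(resid, 0.0, hi, xtol=1e-15, rtol=8.9e-16)
    if abs(resid(cp)) > 1e-9 * max(1.0, loading):
        raise ArithmeticError(f"Cp solve residual {resid(cp):.3e} too large")
    return cp
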