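"""Stomatal conductance and photosynthesis, coupled through intercellular CO2.

Stomatal conductance follows a multiplicative Jarvis-type model extended
with soil nitrogen and atmospheric CO2 effects: a maximum conductance scaled
by six independent [0, 1] reduction functions of net radiation, air
temperature, VPD, soil water, soil N and CO2.  Net assimilation follows the
Farquhar-von Caemmerer-Berry C3 model with Vcmax and Jmax declining linearly
with plant age.  The two are coupled by solving the supply-demand balance
A(Ci) = (Ca - Ci) * gs / 1.6 for the intercellular CO2 mole fraction Ci.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq

from .drivers import EnvForcing
from .params import PhotoParams, StomatalParams

__all__ = [
    "reduction_factors",
    "jarvis_conductance",
    "farquhar_assimilation",
    "couple_ci",
]

#: ratio of stomatal conductance to water vapour over conductance to CO2
GS_CO2_RATIO = 1.6


def _clip01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


# default reduction-function forms; each maps (value, params) -> [0, 1].
# Alternative forms can be injected through StomatalParams.forms.

def _f_rn(rn: float, p: StomatalParams) -> float:
    # hyperbolic saturation with light
    return _clip01(rn / (rn + p.k_rn)) if rn > 0 else 0.0


def _f_ta(ta: float, p: StomatalParams) -> float:
    # symmetric quadratic about the optimum
    z = (ta - p.T_opt) / p.T_width
    return _clip01(1.0 - z * z)


def _f_vpd(vpd: float, p: StomatalParams) -> float:
    return _clip01(1.0 / (1.0 + p.k_vpd * vpd))


def _f_theta(theta: float, p: StomatalParams) -> float:
    # piecewise linear between wilting point and critical water content
    return _clip01((theta - p.theta_w) / (p.theta_c - p.theta_w))


def _f_n(n: float, p: StomatalParams) -> float:
    # biphasic: declines both for deficient and supra-optimal soil N
    z = (n - p.N_opt) / p.N_width
    return _clip01(1.0 - z * z)


def _f_co2(co2: float, p: StomatalParams) -> float:
    # logarithmic decline above the reference concentration
    if co2 <= p.co2_ref:
        return 1.0
    return _clip01(1.0 - p.s_co2 * math.log(co2 / p.co2_ref))


_DEFAULT_FORMS = {
    "Rn": _f_rn, "Ta": _f_ta, "VPD": _f_vpd,
    "theta": _f_theta, "N": _f_n, "CO2": _f_co2,
}


def reduction_factors(env: EnvForcing, p: StomatalParams) -> tuple[float, ...]:
    """The six environmental reduction factors, each in [0, 1], in the order
    (radiation, temperature, VPD, soil water, soil N, CO2)."""
    forms = {**_DEFAULT_FORMS, **p.forms}
    return (
        forms["Rn"](env.Rn_prime, p),
        forms["Ta"](env.Ta, p),
        forms["VPD"](env.VPD, p),
        forms["theta"](env.theta, p),
        forms["N"](env.N, p),
        forms["CO2"](env.CO2, p),
    )


def jarvis_conductance(env: EnvForcing, p: StomatalParams) -> float:
    """Actual stomatal conductance gs = gs_max * product of reduction factors
    (mol H2O m-2 s-1); always within [0, gs_max]."""
    f = 1.0
    for fi in reduction_factors(env, p):
        f *= fi
    return p.gs_max * f


def _electron_transport(par: float, p: PhotoParams, daa: float) -> float:
    """Potential electron transport rate J from the non-rectangular
    hyperbola theta_J J^2 - (alpha PAR + Jmax) J + alpha PAR Jmax = 0."""
    jmax = p.jmax(daa)
    if par <= 0.0 or jmax <= 0.0:
        return 0.0
    i2 = p.alpha * par
    b = i2 + jmax
    disc = b * b - 4.0 * p.theta_J * i2 * jmax
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * p.theta_J)


def farquhar_assimilation(Ci: float, PAR: float, Tleaf: float, daa: float,
                          p: PhotoParams) -> float:
    """Net assimilation A = min(Ac, Aj) - Rd (umol CO2 m-2 s-1).

    Ac is the Rubisco-limited rate, Aj the RuBP-regeneration-limited rate;
    both vanish at the CO2 compensation point, so A(gamma_star) = -Rd.
    ``Tleaf`` is accepted for interface completeness; the kinetic constants
    are held at their reference values (see methods note).
    """
    if Ci < 0:
        raise ValueError("Ci must be >= 0")
    gamma = p.gamma_star
    kco = p.Kc * (1.0 + p.O2 / p.Ko)
    ac = p.vcmax(daa) * (Ci - gamma) / (Ci + kco)
    j = _electron_transport(PAR, p, daa)
    if j > 0.0:
        aj = (j / 4.0) * (Ci - gamma) / (Ci + 2.0 * gamma)
        a = min(ac, aj)
    else:
        # no light: electron transport is nil, no carboxylation either
        a = min(ac, 0.0)
    return a - p.Rd


def couple_ci(env: EnvForcing, gs: float, p: PhotoParams, daa: float,
              par: float | None = None) -> tuple[float, float]:
    """Solve the diffusion-biochemistry balance for (Ci, Pn).

    Finds Ci such that A(Ci) = (Ca - Ci) * gs / 1.6 by a bracketed scalar
    root solve on [gamma_star, Ca] (extended above Ca when net respiration
    makes the leaf a CO2 source).  Returns (Ci, Pn) with Pn = A(Ci) in
    umol CO2 m-2 s-1.  For gs <= 0 the stomata are closed: returns
    (nan, -Rd).
    """
    ca = env.CO2
    if par is None:
        par = p.par_factor * env.Rn_prime
    if gs <= 0.0:
        return (math.nan, -p.Rd)
    gc = gs / GS_CO2_RATIO

    def resid(ci: float) -> float:
        return farquhar_assimilation(ci, par, env.Ta, daa, p) - (ca - ci) * gc

    lo, hi = p.gamma_star, ca
    if resid(hi) < 0.0:
        # respiration exceeds assimilation at ambient: Ci rises above Ca
        lo, hi = ca, ca + max(50.0, 10.0 * p.Rd / gc if gc > 0 else 50.0)
        while resid(hi) < 0.0 and hi < 100 * ca:
            hi *= 2.0
    if resid(lo) > 0.0:
        # demand below supply everywhere in bracket (e.g. gamma_star >= Ca)
        ci = lo
        return (ci, farquhar_assimilation(ci, par, env.Ta, daa, p))
    ci = brentq(resid, lo, hi, xtol=1e-12, rtol=8.9e-16)
    if abs(resid(ci)) > 1e-9:
        raise ArithmeticError(
            f"Ci solve failed: residual {resid(ci):.3e} at Ci={ci:.6f} "
            f"(gs={gs:.4f}, Ca={ca:.1f}, PAR={par:.1f}, daa={daa:.2f})")
    return (ci, farquhar_assimilation(ci, par, env.Ta, daa, p))
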