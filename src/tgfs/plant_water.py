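"""Canopy transpiration and soil/stem water potentials.

Water flow through the plant is treated as quasi-steady: the root water
uptake rate equals the canopy transpiration rate at every hour, and the stem
water potential follows from the soil water potential minus the resistive
drawdown psi_stem = psi_soil - Rp * Tr.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .params import WaterParams

__all__ = [
    "transpiration_rate",
    "soil_water_potential",
    "stem_water_potential",
]

log = logging.getLogger(__name__)

#: molar mass of water, g mol-1
M_WATER = 18.015

# head in cm of water to MPa
_CM_H2O_TO_MPA = 9.80665e-5


def transpiration_rate(VPD: float, gs: float, LA: float,
                       P_atm: float = 101.325) -> float:
    """Canopy transpiration Tr (g h-1).

    Mole-fraction formulation: the leaf-to-air water vapour mole-fraction
    difference is VPD / P_atm, so
    Tr = gs * (VPD / P_atm) * LA * 18.015 * 3600.
    """
    if VPD < 0 or gs < 0 or LA < 0:
        raise ValueError("VPD, gs and LA must be >= 0")
    return gs * (VPD / P_atm) * LA * M_WATER * 3600.0


def soil_water_potential(theta: float, p: WaterParams) -> float:
    """Soil water potential psi_soil (MPa, <= 0) from volumetric water
    content via the configured retention curve.

    Strictly increasing in theta on (theta_res, theta_sat]; below the
    residual content the potential saturates at ``p.psi_min`` with a
    warning, above saturation it is clipped to theta_sat.
    """
    if theta > p.theta_sat:
        theta = p.theta_sat
    if theta <= p.theta_res:
        log.warning("theta=%.4f at or below residual %.4f; psi clamped to %.2f MPa",
                    theta, p.theta_res, p.psi_min)
        return p.psi_min
    if p.retention == "van_genuchten":
        m = 1.0 - 1.0 / p.vg_n
        se = (theta - p.theta_res) / (p.theta_sat - p.theta_res)
        if se >= 1.0:
            return 0.0
        head_cm = (se ** (-1.0 / m) - 1.0) ** (1.0 / p.vg_n) / p.vg_alpha
        psi = -head_cm * _CM_H2O_TO_MPA
    elif p.retention == "campbell":
        psi = p.cb_psi_e * (theta / p.theta_sat) ** (-p.cb_b)
        psi = min(psi, 0.0)
    elif p.retention == "table":
        if not p.table_theta or not p.table_psi:
            raise ValueError("table retention requires table_theta/table_psi")
        psi = float(np.interp(theta, p.table_theta, p.table_psi))
    else:
        raise ValueError(f"unknown retention curve {p.retention!r}")
    return max(psi, p.psi_min)


def stem_water_potential(psi_soil: float, Rp: float, Tr: float) -> float:
    """psi_stem = psi_soil - Rp * Tr (MPa); never above psi_soil for Tr >= 0."""
    if Tr < 0:
        raise ValueError("Tr must be >= 0")
    return psi_soil - Rp * Tr
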