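"""Two-compartment oxygen transport and metabolite kinetics.

Oxygen is tracked as partial pressures in a capillary and a tissue
compartment.  Total oxygen content combines hemoglobin (Hill binding,
capillary) or myoglobin (hyperbolic binding, tissue) with physically
dissolved oxygen; the buffering slopes γ = dO₂/dPO₂ convert content
balances into pressure dynamics.  Muscle consumption follows
Michaelis–Menten kinetics with a very small Michaelis constant, so the
tissue consumes at its baseline rate until oxygen is nearly exhausted.

Two vasoactive metabolites are driven by the oxygenation state:

* intravascular ATP, released by red blood cells in proportion to
  hemoglobin desaturation and degraded at the endothelial surface;
* interstitial adenosine, formed at a low rate under aerobic conditions
  and ten-fold faster once the tissue oxygen tension falls below the
  critical pressure for anaerobic metabolism, and cleared by saturable
  cellular uptake.

Rates are per second, concentrations µM, pressures mmHg.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .circuit import BaselineCalibration
from .constants import OxygenParams

__all__ = [
    "MetabolicState",
    "blood_o2_content",
    "tissue_o2_content",
    "gamma_slopes",
    "metabolic_rate",
    "atp_release",
    "adenosine_formation",
    "metabolite_rhs",
]


@dataclass(frozen=True)
class MetabolicState:
    """Oxygen tensions (mmHg) and metabolite concentrations (µM)."""

    PO2c: float
    PO2t: float
    C_ATP: float
    C_ado: float


def blood_o2_content(PO2: float, p: OxygenParams) -> float:
    """Total blood O₂ content (µM): Hill-bound to hemoglobin + dissolved."""
    PO2 = max(PO2, 0.0)
    Pn = PO2**p.n_hill
    return 4.0 * p.C_Hb * Pn / (Pn + p.P50_Hb**p.n_hill) + p.w_b * p.alpha * PO2


def tissue_o2_content(PO2: float, p: OxygenParams) -> float:
    """Total tissue O₂ content (µM): myoglobin-bound + dissolved."""
    PO2 = max(PO2, 0.0)
    return p.C_Mb * PO2 / (PO2 + p.P50_Mb) + p.w_t * p.alpha * PO2


def gamma_slopes(PO2c: float, PO2t: float, p: OxygenParams) -> tuple[float, float]:
    """Buffering slopes ``γ = dO₂/dPO₂`` of the two compartments (µM/mmHg).

    Exact analytic derivatives of the content curves; both are strictly
    positive (the dissolved term bounds them below by ``w·α``).
    """
    PO2c = max(PO2c, 0.0)
    PO2t = max(PO2t, 0.0)
    K = p.P50_Hb**p.n_hill
    gamma_c = (
        4.0 * p.C_Hb * p.n_hill * K * PO2c ** (p.n_hill - 1.0) / (PO2c**p.n_hill + K) ** 2
        + p.w_b * p.alpha
    )
    gamma_t = p.C_Mb * p.P50_Mb / (PO2t + p.P50_Mb) ** 2 + p.w_t * p.alpha
    return gamma_c, gamma_t


def metabolic_rate(O2t: float, V_max_m: float, p: OxygenParams) -> float:
    """Muscle O₂ consumption ``V_max,m·O2t/(O2t + K_m)`` (µM/s)."""
    if O2t < 0:
        raise ValueError("O2t must be non-negative")
    return V_max_m * O2t / (O2t + p.K_m_O2)


def atp_release(PO2c: float, p: OxygenParams) -> float:
    """RBC ATP release rate (µM/s), decreasing with hemoglobin saturation."""
    PO2c = max(PO2c, 0.0)
    Pn = PO2c**p.n_hill
    return p.R0 * (1.0 - p.R1 * Pn / (Pn + p.P50_Hb**p.n_hill))


def adenosine_formation(PO2t: float, p: OxygenParams) -> float:
    """Interstitial adenosine formation rate (µM/s).

    Two-mode: the low aerobic rate for ``PO2t ≥ PO2_cr`` and the high
    anaerobic rate below.  A smooth logistic blend of width
    ``ado_switch_width`` replaces the hard switch when that width is
    positive (off by default).
    """
    if p.ado_switch_width > 0.0:
        u = (PO2t - p.PO2_cr) / p.ado_switch_width
        if u >= 0:
            s = 1.0 / (1.0 + math.exp(-u))
        else:
            eu = math.exp(u)
            s = eu / (1.0 + eu)
        return p.F_ado_high + (p.F_ado_low - p.F_ado_high) * s
    return p.F_ado_low if PO2t >= p.PO2_cr else p.F_ado_high


def metabolite_rhs(
    state: MetabolicState,
    f: float,
    calib: BaselineCalibration,
    p: OxygenParams,
) -> tuple[float, float, float, float]:
    """Time derivatives of ``(PO2c, PO2t, C_ATP, C_ado)``.

    ``f`` is the perfusion per unit tissue volume (1/s) seen by the
    microcirculation; it multiplies the convective supply of oxygen and
    the plasma wash-in/wash-out of ATP, and is zero during cuff occlusion.
    The ATP balance is written per capillary plasma volume: the capillary
    flow is ``f/v_c``, the plasma fractions appear through the tube and
    discharge hematocrits, and degradation scales with the surface-to-
    plasma-volume ratio ``2/(r_c(1−h_t))``.
    """
    gamma_c, gamma_t = gamma_slopes(state.PO2c, state.PO2t, p)
    o2c = blood_o2_content(state.PO2c, p)
    o2t = tissue_o2_content(state.PO2t, p)
    J_diff = p.alpha * calib.D * (state.PO2c - state.PO2t)
    VO2 = metabolic_rate(max(o2t, 0.0), calib.V_max_m, p)
    dPO2c = (f * (calib.O2_art - o2c) - J_diff) / (p.v_c * gamma_c)
    dPO2t = (J_diff - VO2) / (p.v_t * gamma_t)
    plasma = 1.0 - p.h_t
    dC_ATP = (
        (f / p.v_c) * (1.0 - p.h_d) / plasma * (p.C_ATP_in - state.C_ATP)
        + p.h_t / plasma * atp_release(state.PO2c, p)
        - 2.0 * p.k_d / (p.r_c * plasma) * state.C_ATP
    )
    dC_ado = (
        adenosine_formation(state.PO2t, p)
        - p.V_max_ado * state.C_ado / (state.C_ado + p.K_m_ado)
    )
    return dPO2c, dPO2t, dC_ATP, dC_ado
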