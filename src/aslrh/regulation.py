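"""Smooth-muscle activation and the four vasoregulation mechanisms.

Four regulatory states — myogenic, shear, intravascular ATP, interstitial
adenosine — each relax toward a stimulus with first-order kinetics.  Their
weighted sum plus a constant offset is the total regulatory influence ``z``,
and the activation of the arteriolar smooth muscle is a sigmoid of ``z``.

Sign convention: elevated wall tension (myogenic) *raises* the activation
(constriction), while elevated shear and accumulation of ATP or adenosine
*lower* it (dilation).  During ischemia the metabolite states grow and the
muscle de-activates, which is what produces reactive hyperemia on release.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .circuit import BaselineCalibration
from .constants import RegulationParams

__all__ = [
    "RegulatoryState",
    "activation",
    "total_influence",
    "stimuli",
    "regulation_rhs",
]


@dataclass(frozen=True)
class RegulatoryState:
    """The four dimensionless regulatory states (all zero at baseline)."""

    x_myo: float = 0.0
    x_sh: float = 0.0
    x_ATP: float = 0.0
    x_ado: float = 0.0


def activation(z: float) -> float:
    """Smooth-muscle activation ``A = 1/(1 + e^(−2z))``, strictly in (0, 1)."""
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-2.0 * z))
    ez = math.exp(2.0 * z)  # avoid overflow for very negative z
    return ez / (1.0 + ez)


def total_influence(x: RegulatoryState, p: RegulationParams) -> float:
    """Total regulatory influence ``z``.

    ``z = x_init + g_myo·x_myo − g_sh·x_sh − g_ATP·x_ATP − g_ado·x_ado``;
    the dilatory mechanisms enter with negative sign so that metabolite
    accumulation and elevated shear de-activate the muscle.
    """
    return (
        p.x_init
        + p.g_myo * x.x_myo
        - p.g_sh * x.x_sh
        - p.g_ATP * x.x_ATP
        - p.g_ado * x.x_ado
    )


def stimuli(
    T: float,
    Q_v: float,
    r_a: float,
    C_ATP: float,
    C_ado: float,
    calib: BaselineCalibration,
    p: RegulationParams,
    cuff_on: bool = False,
) -> tuple[float, float, float, float]:
    """Stimulus functions ``(y_myo, y_sh, y_ATP, y_ado)``.

    Each stimulus is the deviation of its driving quantity from the
    calibrated baseline, scaled so that the resting state gives zero:
    wall tension for the myogenic arm, ``Q_v/r_a³`` (proportional to wall
    shear stress) for the shear arm, and the two metabolite concentrations.
    With the cuff inflated the vasculature under the cuff is collapsed and
    the shear drive is exactly ``−1`` (zero flow).
    """
    y_myo = p.s_my * (T - calib.T_0)
    if cuff_on:
        y_sh = -1.0
    else:
        y_sh = calib.s_sh_scale * Q_v / r_a**3 - 1.0
    y_ATP = p.s_ATP * (C_ATP - calib.C_ATP0)
    y_ado = p.s_ado * (C_ado - calib.C_ado0)
    return y_myo, y_sh, y_ATP, y_ado


def regulation_rhs(
    x: RegulatoryState,
    y: tuple[float, float, float, float],
    p: RegulationParams,
) -> tuple[float, float, float, float]:
    """First-order relaxation ``dx_i/dt = (y_i − x_i)/τ_i`` of each state."""
    return (
        (y[0] - x.x_myo) / p.tau_myo,
        (y[1] - x.x_sh) / p.tau_sh,
        (y[2] - x.x_ATP) / p.tau_ATP,
        (y[3] - x.x_ado) / p.tau_ado,
    )
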