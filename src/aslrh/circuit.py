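"""Vessel mechanics and the lumped flow circuit of the lower leg.

The calf circulation is modelled as three vascular segments in series —
popliteal artery, arteriolar bed, veins — each a resistor–capacitor unit.
Only the arteriolar segment is adjustable: its resistance and volume follow
power laws of the arteriolar radius ``r_a``, and the radius itself obeys a
wall tension balance (Laplace's law) between the transmural pressure load
and the sum of passive elastic tension and active smooth-muscle tension
scaled by the activation level ``A``.

Each segment's resistance is split in half around its mid-pressure node, so
the flow into the arteriolar bed is ``Q_a = (P_p − P_a)/(R_a/2)`` and the
flow delivered to the tissue (what an ASL measurement sees) is
``Q_v = (P_a − P_v)/((R_a + R_v)/2)``.

Canonical units throughout: mmHg, s, mL, cm (see :mod:`aslrh.constants`).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .constants import ModelConstants

__all__ = [
    "CalibrationError",
    "CircuitState",
    "BaselineCalibration",
    "poiseuille_resistance",
    "wall_thickness",
    "elastic_tension",
    "muscular_tension",
    "wall_tension",
    "pressure_from_radius",
    "radius_from_pressure",
    "arteriolar_RV",
    "segment_flows",
    "circuit_rhs",
]

#: bracket for the inverse tension solve (cm)
RADIUS_BRACKET = (10e-4, 400e-4)

#: perfusion conversion, (mL/s)/mL tissue -> mL/100 g/min
PERFUSION_SCALE = 6000.0


class CalibrationError(RuntimeError):
    """No physical baseline state exists for the requested conditions."""


@dataclass(frozen=True)
class CircuitState:
    """Dynamic state of the flow circuit.

    ``P_p``: end-arterial perfusion pressure (mmHg); ``r_a``: arteriolar
    radius (cm); ``P_v``: mid-venous pressure (mmHg).
    """

    P_p: float
    r_a: float
    P_v: float

    def __post_init__(self) -> None:
        if not (self.r_a > 0 and math.isfinite(self.P_p) and math.isfinite(self.P_v)):
            raise ValueError("invalid circuit state")


@dataclass(frozen=True)
class BaselineCalibration:
    """Quantities fixed by the baseline (resting steady state) calibration.

    Produced by :func:`aslrh.simulator.calibrate`; every field is in
    canonical units.  ``r_ref`` is the anchor radius of the arteriolar
    power laws (the group-average resting radius, where
    ``R_a = delta_P_a / Q_r`` and ``R_a·C_a = tau_a``); ``r_base`` is the
    subject's own resting radius, which coincides with ``r_ref`` at the
    group-average resting perfusion.
    """

    K_R: float          # mmHg·s/mL · cm⁴
    K_V: float          # mL/cm²
    R_p: float          # mmHg·s/mL (includes any stenosis scaling)
    C_p: float          # mL/mmHg
    R_v: float          # mmHg·s/mL
    C_v: float          # mL/mmHg
    P_ai: float         # arterial input pressure, mmHg
    r_ref: float        # cm
    r_base: float       # cm
    P_p_base: float
    P_a_base: float
    P_v_base: float
    Q_base: float       # mL/s
    f_base: float       # 1/s  (perfusion per unit tissue volume)
    A_base: float
    x_init: float
    T_0: float          # baseline wall tension, mmHg·cm
    s_sh_scale: float   # shear stimulus scale, cm³·s/mL
    C_ATP0: float       # µM
    C_ado0: float       # µM
    V_max_m: float      # µM/s
    D: float            # O₂ diffusion capacity per tissue volume, 1/s
    O2_art: float       # µM
    PO2c_base: float    # mmHg
    PO2t_base: float    # mmHg


def poiseuille_resistance(radius: float, length: float, viscosity: float) -> float:
    """Poiseuille flow resistance ``8ηl/(πr⁴)`` of a cylindrical vessel.

    Parameters are in cm and mmHg·s; the result is in mmHg·s/mL (divide
    by 60 for the conventional mmHg·min/mL).
    """
    if radius <= 0 or length <= 0 or viscosity <= 0:
        raise ValueError("radius, length and viscosity must be positive")
    return 8.0 * viscosity * length / (math.pi * radius**4)


def wall_thickness(r_a: float, c: ModelConstants) -> float:
    """Arteriolar wall thickness at inner radius ``r_a``.

    Follows from conservation of wall cross-section area:
    ``(r_a + h_a)² − r_a²`` is the same as for the unstressed wall, so the
    wall thins as the vessel dilates.
    """
    if r_a <= 0:
        raise ValueError("r_a must be positive")
    outer = math.sqrt(r_a * r_a + 2.0 * c.r_a0 * c.h_a0 + c.h_a0 * c.h_a0)
    return outer - r_a


def elastic_tension(r_a: float, c: ModelConstants) -> float:
    """Passive elastic wall tension T_e (mmHg·cm).

    Exponential stress–strain law times the current wall thickness; the
    resting value is negative (the unstressed wall is under compression at
    the resting radius) and rises steeply with distension.
    """
    strain = (r_a - c.r_a0) / c.r_a0
    return (c.sigma_1 * math.exp(c.k_e * strain) - c.sigma_2) * wall_thickness(r_a, c)


def muscular_tension(r_a: float, c: ModelConstants) -> float:
    """Maximal active smooth-muscle tension T_m (mmHg·cm).

    Bell-shaped in the radius with maximum ``T_m0`` at ``r_am``; the actual
    active tension is ``A·T_m`` with activation ``A ∈ [0, 1]``.
    """
    if r_a <= 0:
        raise ValueError("r_a must be positive")
    return c.T_m0 * math.exp(-abs((r_a - c.r_am) / (c.r_at - c.r_am)) ** c.n_m)


def wall_tension(r_a: float, A: float, c: ModelConstants) -> float:
    """Total wall tension ``T_e + A·T_m`` at radius ``r_a`` (mmHg·cm)."""
    return elastic_tension(r_a, c) + A * muscular_tension(r_a, c)


def pressure_from_radius(r_a: float, A: float, c: ModelConstants) -> float:
    """Mid-arteriolar pressure balancing the wall tension at radius ``r_a``.

    Laplace's law with the intramuscular pressure acting on the outer
    wall: ``T = P_a·r_a − P_im·(r_a + h_a) = T_e + A·T_m`` solved for P_a.
    """
    if not 0.0 <= A <= 1.0:
        raise ValueError("activation must lie in [0, 1]")
    h = wall_thickness(r_a, c)
    return (wall_tension(r_a, A, c) + c.P_im * (r_a + h)) / r_a


def radius_from_pressure(
    P_a: float,
    A: float,
    c: ModelConstants,
    bracket: tuple[float, float] = RADIUS_BRACKET,
) -> float:
    """Arteriolar radius at which the wall tension balances pressure ``P_a``.

    Bracketed root solve of :func:`pressure_from_radius`; raises
    :class:`CalibrationError` when no equilibrium radius exists in the
    bracket (never clamps silently).
    """
    lo, hi = bracket

    def gap(r: float) -> float:
        return pressure_from_radius(r, A, c) - P_a

    try:
        if gap(lo) * gap(hi) > 0:
            raise ValueError
        return brentq(gap, lo, hi, xtol=1e-10)
    except ValueError as exc:
        raise CalibrationError(
            f"no equilibrium radius in [{lo * 1e4:.0f}, {hi * 1e4:.0f}] µm "
            f"for P_a={P_a:.2f} mmHg, A={A:.3f}"
        ) from exc


def arteriolar_RV(r_a: float, calib: BaselineCalibration) -> tuple[float, float]:
    """Arteriolar resistance ``K_R/r_a⁴`` and volume ``K_V·r_a²``."""
    if r_a <= 0:
        raise ValueError("r_a must be positive")
    return calib.K_R / r_a**4, calib.K_V * r_a**2


def segment_flows(
    state: CircuitState,
    A: float,
    calib: BaselineCalibration,
    c: ModelConstants,
) -> tuple[float, float, float]:
    """Arteriolar inflow, tissue flow and ASL perfusion for a circuit state.

    Returns ``(Q_a, Q_v, f_ASL)`` with flows in mL/s and perfusion
    ``f_ASL = Q_v/V_m`` in mL/100g/min.  The mid-arteriolar pressure is
    obtained from the tension balance at the current radius and activation.
    """
    P_a = pressure_from_radius(state.r_a, A, c)
    R_a, _ = arteriolar_RV(state.r_a, calib)
    Q_a = 2.0 * (state.P_p - P_a) / R_a
    Q_v = 2.0 * (P_a - state.P_v) / (R_a + calib.R_v)
    return Q_a, Q_v, Q_v / c.V_m * PERFUSION_SCALE


def circuit_rhs(
    state: CircuitState,
    A: float,
    cuff_on: bool,
    calib: BaselineCalibration,
    c: ModelConstants,
) -> tuple[float, float, float]:
    """Time derivatives ``(dP_p/dt, dr_a/dt, dP_v/dt)`` of the circuit.

    With the cuff inflated both end switches are open (``Q_ai = Q_vo = 0``)
    and the circuit is a closed system that only redistributes volume
    internally.  The radius equation is the arteriolar volume balance
    ``dV_a/dt = 2·K_V·r_a·dr_a/dt = Q_a − Q_v``.
    """
    Q_a, Q_v, _ = segment_flows(state, A, calib, c)
    if cuff_on:
        Q_ai = 0.0
        Q_vo = 0.0
    else:
        Q_ai = (calib.P_ai - state.P_p) / calib.R_p
        Q_vo = (state.P_v - c.P_vo) / calib.R_v
    return (
        (Q_ai - Q_a) / calib.C_p,
        (Q_a - Q_v) / (2.0 * calib.K_V * state.r_a),
        (Q_v - Q_vo) / calib.C_v,
    )
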