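"""Model constants and configuration handling.

Every quantity is stored in one canonical unit system:

    pressure  mmHg
    time      s
    volume    mL
    length    cm
    amount    µM (concentrations), mL/s (flows)

The published constant tables mix µm, cm, minutes and litres; those units
are accepted only at the configuration boundary (:func:`ModelConstants.from_table`
and the YAML loader) and converted on entry.  Perfusion is reported to users
in the conventional mL/100g/min (muscle density taken as 1 g/mL, so
mL/100g/min and mL/100mL/min are used interchangeably).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelConstants",
    "RegulationParams",
    "OxygenParams",
    "load_config",
    "resolve_config",
]

_MIN = 60.0  # seconds per minute
_UM = 1e-4   # cm per µm


@dataclass(frozen=True)
class ModelConstants:
    """Fixed physiological and geometric constants of the flow circuit.

    Defaults reproduce the published constant table for the lower leg.
    All fields are in the canonical units (mmHg, s, mL, cm).

    Attributes
    ----------
    P_vo : venous output pressure (mmHg).
    P_im : intramuscular fluid pressure (mmHg).
    Q_r : resting flow rate to the lower leg (mL/s).
    V_m : volume of one lower leg (mL).
    eta_b : blood viscosity (mmHg·s).
    r_a0, h_a0 : inner radius and wall thickness of the unstressed
        arteriolar wall (cm); these parameterise the wall-volume
        conservation law and the elastic tension curve.
    sigma_1, sigma_2, k_e : elastic tension constants (mmHg, mmHg, –).
    T_m0 : maximal muscular tension (mmHg·cm).  The published table prints
        the unit as mmHg·s, which is not a tension; the value is used in
        the same units as the elastic tension.
    r_am, r_at, n_m : muscular tension curve constants (cm, cm, –).
    r_p, l_p : popliteal artery radius and length (cm).
    delta_P_a : assumed resting arteriolar pressure drop P_p − P_v (mmHg).
    P_a_rest : assumed resting mid-arteriolar pressure (mmHg).
    venous_drop : assumed resting venous pressure drop P_v − P_vo (mmHg).
    x_init_ref : regulatory offset of the group-average resting state
        (dimensionless); anchors the arteriolar resistance/volume power
        laws, see :func:`aslrh.simulator.calibrate`.
    tau_p_default : popliteal time constant R_p·C_p (s) when no subject
        value is given.
    tau_v : venous time constant R_v·C_v (s).
    tau_a : arteriolar time constant R_a·C_a at baseline (s).
    """

    P_vo: float = 14.0
    P_im: float = 10.0
    Q_r: float = 144.0 / _MIN
    V_m: float = 3000.0
    eta_b: float = 3e-5
    r_a0: float = 75.0 * _UM
    h_a0: float = 25.0 * _UM
    sigma_1: float = 11.19
    sigma_2: float = 52.51
    k_e: float = 4.5
    T_m0: float = 3.0
    r_am: float = 128.0 * _UM
    r_at: float = 174.0 * _UM
    n_m: float = 1.75
    r_p: float = 0.25
    l_p: float = 40.0
    delta_P_a: float = 70.0
    P_a_rest: float = 50.0
    venous_drop: float = 1.0
    x_init_ref: float = 0.45
    tau_p_default: float = 5.0
    tau_v: float = 10.0
    tau_a: float = 1.0

    # conversion factors from the units used in the published table
    _TABLE_SCALE = {
        "Q_r": 1.0 / _MIN,   # mL/min -> mL/s
        "V_m": 1000.0,       # L -> mL
        "r_a0": _UM,
        "h_a0": _UM,
        "r_am": _UM,
        "r_at": _UM,
    }

    @classmethod
    def from_table(cls, values: Mapping[str, float]) -> "ModelConstants":
        """Build constants from a mapping keyed by the published symbols.

        Values are interpreted in the table's units (mL/min for ``Q_r``,
        L for ``V_m``, µm for the four arteriolar radii/thicknesses) and
        converted to canonical units.  Unknown keys raise ``KeyError``.
        """
        fields = {f.name for f in dataclasses.fields(cls)}
        kwargs: dict[str, float] = {}
        for key, val in values.items():
            if key not in fields:
                raise KeyError(f"unknown model constant {key!r}")
            kwargs[key] = float(val) * cls._TABLE_SCALE.get(key, 1.0)
        return cls(**kwargs)


@dataclass(frozen=True)
class RegulationParams:
    """Gains, time constants and stimulus scales of the four regulators.

    The wall-derived mechanisms (myogenic, shear) use fixed unit gains;
    the metabolite-derived gains and time constants are subject-specific
    and default to the healthy-group means.  ``x_init`` is the constant
    offset of the total regulatory influence; it is solved by the baseline
    calibration from the subject's resting perfusion and overridden there.

    Units: time constants s; ``s_my`` (mmHg·cm)⁻¹; ``s_ATP``/``s_ado`` µM⁻¹.
    """

    g_myo: float = 1.0
    g_sh: float = 1.0
    g_ATP: float = 15.66
    g_ado: float = 4.18
    tau_myo: float = 6.0
    tau_sh: float = 60.0
    tau_ATP: float = 15.86
    tau_ado: float = 43.20
    s_my: float = 3.33
    s_ATP: float = 2.5
    s_ado: float = 0.61
    x_init: float = 0.0

    def __post_init__(self) -> None:
        for name in ("g_myo", "g_sh", "g_ATP", "g_ado"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("tau_myo", "tau_sh", "tau_ATP", "tau_ado"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class OxygenParams:
    """Constants of the two-compartment oxygen/metabolite model.

    Rates are stored per second (the published values are per minute and
    converted here once).  ``PO2_art``, ``PO2c_base`` and ``PO2t_base``
    are the assumed arterial, resting capillary and resting tissue oxygen
    tensions used by the baseline calibration to fix the diffusion
    capacity ``D`` and the maximal metabolic rate; they are not printed
    in the source table and are standard resting-muscle values.

    Attributes (units)
    ------------------
    alpha : O₂ solubility in blood/tissue water (µM/mmHg).
    v_c, v_t : capillary and tissue volume fractions (–).
    C_Hb : blood hemoglobin concentration (µM of Hb tetramer).
    C_Mb : tissue myoglobin concentration (µM).
    w_b, w_t : water fractions of blood and tissue (–).
    P50_Hb, n_hill : hemoglobin half-saturation pressure (mmHg) and Hill
        coefficient.
    P50_Mb : myoglobin half-saturation pressure (mmHg; standard human
        value, not stated in the source).
    K_m_O2 : Michaelis constant of muscle O₂ consumption (µM).
    PO2_cr : critical tissue O₂ tension for anaerobic metabolism (mmHg).
    R0, R1 : RBC ATP release constants (µM/s, –).
    C_ATP_in : arterial plasma ATP concentration (µM).
    r_c : capillary radius (cm).
    h_t, h_d : tube and discharge hematocrit (–).
    k_d : endothelial ATP degradation constant (cm/s).
    V_max_ado, K_m_ado : adenosine clearance kinetics (µM/s, µM).
    F_ado_low, F_ado_high : adenosine formation rates above/below the
        critical O₂ tension (µM/s).
    C_ado_base : nominal baseline interstitial adenosine (µM).
    ado_switch_width : optional logistic blending width (mmHg) for the
        adenosine formation switch; 0 keeps the exact two-mode form.
    """

    alpha: float = 1.46
    v_c: float = 0.03
    v_t: float = 0.97
    C_Hb: float = 2330.0
    C_Mb: float = 365.0
    w_b: float = 0.8095
    w_t: float = 0.78
    P50_Hb: float = 26.8
    n_hill: float = 2.7
    P50_Mb: float = 2.39
    K_m_O2: float = 0.7
    PO2_cr: float = 10.0
    R0: float = 84.0 / _MIN
    R1: float = 0.891
    C_ATP_in: float = 0.1
    r_c: float = 3.0 * _UM
    h_t: float = 0.4
    h_d: float = 0.3
    k_d: float = 2e-4
    V_max_ado: float = 100.0 / _MIN
    K_m_ado: float = 200.0
    F_ado_low: float = 0.05 / _MIN
    F_ado_high: float = 0.5 / _MIN
    C_ado_base: float = 0.1
    PO2_art: float = 95.0
    PO2c_base: float = 40.0
    PO2t_base: float = 30.0
    ado_switch_width: float = 0.0


def resolve_config(config: Mapping[str, Any] | None) -> tuple[
    ModelConstants, RegulationParams, OxygenParams
]:
    """Resolve a nested config mapping into the three parameter sets.

    ``config`` may contain the sections ``constants`` (published-table
    units, see :meth:`ModelConstants.from_table`), ``regulation`` and
    ``oxygen`` (canonical units).  Missing sections take the defaults.
    """
    config = dict(config or {})
    constants = ModelConstants.from_table(config.pop("constants", {}))
    regulation = RegulationParams(**config.pop("regulation", {}))
    oxygen = OxygenParams(**config.pop("oxygen", {}))
    if config:
        raise KeyError(f"unknown config sections: {sorted(config)}")
    return constants, regulation, oxygen


def load_config(path: str | Path) -> tuple[ModelConstants, RegulationParams, OxygenParams]:
    """Load a YAML config file (see :func:`resolve_config` for the schema)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return resolve_config(data)
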