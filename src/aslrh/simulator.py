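"""Baseline calibration, the full 11-state model, and cuff-protocol simulation.

State vector (canonical units):

    [P_p, r_a, P_v, x_myo, x_sh, x_ATP, x_ado, PO2c, PO2t, C_ATP, C_ado]

The baseline calibration solves the resting steady state of the complete
coupled system at the subject's resting perfusion and fixes every derived
constant (arteriolar power laws, segment R/C values, regulatory reference
levels, metabolic rates) so that the resting state is an exact fixed point
of the dynamics.  A cuff protocol is then simulated by integrating the
system through baseline → occlusion → release, with the two circuit
switches opened and closed by restarting the integration at the switch
times.  Time zero is cuff inflation; release is at ``t_cuff``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import (
    PERFUSION_SCALE,
    BaselineCalibration,
    CalibrationError,
    arteriolar_RV,
    muscular_tension,
    elastic_tension,
    poiseuille_resistance,
    pressure_from_radius,
    radius_from_pressure,
    wall_tension,
    wall_thickness,
)
from .constants import ModelConstants, OxygenParams, RegulationParams
from .oxygen import (
    atp_release,
    blood_o2_content,
    tissue_o2_content,
)
from .regulation import activation

__all__ = [
    "SubjectParams",
    "CuffProtocol",
    "PerfusionTrace",
    "SimulationResult",
    "HEALTHY_MEANS",
    "HEALTHY_BOUNDS",
    "PATIENT_BOUNDS",
    "calibrate",
    "simulate",
    "characterize",
]

STATE_NAMES = (
    "P_p", "r_a", "P_v",
    "x_myo", "x_sh", "x_ATP", "x_ado",
    "PO2c", "PO2t", "C_ATP", "C_ado",
)


@dataclass(frozen=True)
class SubjectParams:
    """Subject-specific free parameters of the model.

    ``f_r`` is the resting perfusion (mL/100g/min); ``g_ATP``/``g_ado``
    and ``tau_ATP``/``tau_ado`` the metabolite regulation gains and time
    constants (–, s); ``tau_p`` the popliteal time constant R_p·C_p at
    the standard popliteal resistance (s); ``R_p_scale`` the popliteal
    resistance expressed as a multiple of the Poiseuille standard value
    (1 for a healthy artery, >1 for stenosis).

    Defaults are the healthy-group mean estimates.
    """

    f_r: float = 4.95
    g_ATP: float = 15.66
    g_ado: float = 4.18
    tau_ATP: float = 15.86
    tau_ado: float = 43.20
    tau_p: float = 4.25
    R_p_scale: float = 1.0


HEALTHY_MEANS = SubjectParams()

#: fitting bounds for the healthy two-step schedule
HEALTHY_BOUNDS: Mapping[str, tuple[float, float]] = {
    "f_r": (2.0, 10.0),
    "g_ATP": (1.0, 20.0),
    "g_ado": (1.0, 15.0),
    "tau_ATP": (6.0, 24.0),
    "tau_ado": (12.0, 60.0),
    "tau_p": (1.5, 30.0),
}

#: fitting bounds for the single-step patient schedule
PATIENT_BOUNDS: Mapping[str, tuple[float, float]] = {
    "f_r": (3.0, 8.0),
    "g_ATP": (1.0, 12.0),
    "tau_ATP": (12.0, 36.0),
    "tau_p": (1.5, 25.0),
    "R_p_scale": (1.0, 6.0),
}


@dataclass(frozen=True)
class CuffProtocol:
    """Timing of a cuff occlusion experiment.

    ``t_baseline`` seconds of pre-inflation acquisition, ``t_cuff``
    seconds of occlusion, ``t_recovery`` seconds after release; samples
    every ``dt_sample`` seconds (the ASL repetition time).
    """

    t_baseline: float = 120.0
    t_cuff: float = 120.0
    t_recovery: float = 300.0
    dt_sample: float = 3.35

    def __post_init__(self) -> None:
        if min(self.t_baseline, self.t_cuff, self.t_recovery, self.dt_sample) <= 0:
            raise ValueError("all protocol durations must be positive")

    def sample_times(self, include_cuff: bool = True) -> np.ndarray:
        """Acquisition grid from ``−t_baseline`` to ``t_cuff + t_recovery``."""
        t = np.arange(-self.t_baseline, self.t_cuff + self.t_recovery, self.dt_sample)
        if not include_cuff:
            t = t[(t < 0.0) | (t >= self.t_cuff)]
        return t

    def phase_of(self, t: np.ndarray) -> np.ndarray:
        """Label each time as ``baseline``, ``cuff`` or ``recovery``."""
        t = np.asarray(t, dtype=float)
        out = np.where(t < 0.0, "baseline", np.where(t < self.t_cuff, "cuff", "recovery"))
        return out.astype(object)


@dataclass
class PerfusionTrace:
    """A sampled perfusion–time curve with its protocol annotation.

    ``t`` in seconds (0 = cuff inflation), ``f`` in mL/100g/min.  Samples
    inside the cuff window may be absent, as in real acquisitions.
    """

    t: np.ndarray
    f: np.ndarray
    protocol: CuffProtocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.t.shape != self.f.shape or self.t.ndim != 1:
            raise ValueError("t and f must be matching 1-D arrays")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.t < 0.0

    @property
    def post_release_mask(self) -> np.ndarray:
        return self.t >= self.protocol.t_cuff

    def baseline_sigma2(self) -> float:
        """Variance of the pre-cuff baseline samples (noise estimate)."""
        base = self.f[self.baseline_mask]
        if base.size < 2:
            raise ValueError("trace has fewer than two baseline samples")
        return float(np.var(base, ddof=1))


def _reference_radius(c: ModelConstants) -> float:
    """Anchor radius of the arteriolar power laws.

    The group-average resting state is defined by the empirical regulatory
    offset ``x_init_ref`` and the assumed resting mid-arteriolar pressure;
    the radius solving the wall tension balance there is the anchor at
    which ``R_a = delta_P_a/Q_r`` and ``R_a·C_a = tau_a``.  (The published
    constant table's unstressed radius parameterises the wall mechanics
    but is *not* the operating radius: at rest the pressurised, partially
    activated arteriole sits well below it.)
    """
    A_ref = activation(c.x_init_ref)
    return radius_from_pressure(c.P_a_rest, A_ref, c)


def calibrate(
    subject: SubjectParams,
    constants: ModelConstants | None = None,
    regulation: RegulationParams | None = None,
    oxygen: OxygenParams | None = None,
) -> BaselineCalibration:
    """Solve the resting steady state and fix all derived constants.

    The popliteal and venous R/C values follow the published rules
    (Poiseuille popliteal resistance times any stenosis scaling; venous
    resistance from the 1 mmHg venous drop at the reference flow; venous
    and arteriolar time constants fixed).  The arterial input pressure is
    ledger-derived and held constant.  The subject's resting flow
    ``f_r·V_m`` is then imposed on the circuit, which determines the
    resting radius, pressures, activation and hence the regulatory offset
    ``x_init``; finally the oxygen/metabolite sub-model is calibrated so
    the resting state is an exact fixed point.

    Raises :class:`~aslrh.circuit.CalibrationError` when no physical
    steady state exists (required activation outside (0, 1) or radius
    outside the solve bracket).
    """
    c = constants or ModelConstants()
    oxy = oxygen or OxygenParams()

    Q_base = subject.f_r / PERFUSION_SCALE * c.V_m
    if Q_base <= 0:
        raise CalibrationError("resting perfusion must be positive")

    R_p_std = poiseuille_resistance(c.r_p, c.l_p, c.eta_b)
    R_p = subject.R_p_scale * R_p_std
    C_p = subject.tau_p / R_p_std  # compliance fixed; stenosis scales tau
    R_v = c.venous_drop / c.Q_r
    C_v = c.tau_v / R_v

    r_ref = _reference_radius(c)
    R_a_ref = c.delta_P_a / c.Q_r
    K_R = R_a_ref * r_ref**4
    C_a_ref = c.tau_a / R_a_ref
    K_V = C_a_ref * c.delta_P_a / r_ref**2

    P_ai = c.P_vo + c.venous_drop + c.delta_P_a + c.Q_r * R_p_std

    # impose the subject's resting flow on the circuit
    P_p = P_ai - Q_base * R_p
    P_v = c.P_vo + Q_base * R_v
    R_a = (P_p - P_v) / Q_base - R_v / 2.0
    if R_a <= 0:
        raise CalibrationError("resting flow too high for the available pressure head")
    r_base = (K_R / R_a) ** 0.25
    if not RADIUS_LO < r_base < RADIUS_HI:
        raise CalibrationError(
            f"resting radius {r_base * 1e4:.1f} µm outside the physical bracket"
        )
    P_a = P_p - Q_base * R_a / 2.0

    T_0 = P_a * r_base - c.P_im * (r_base + wall_thickness(r_base, c))
    A_base = (T_0 - elastic_tension(r_base, c)) / muscular_tension(r_base, c)
    if not 0.0 < A_base < 1.0:
        raise CalibrationError(
            f"resting state requires activation {A_base:.3f} outside (0, 1); "
            "no steady state at this resting perfusion"
        )
    x_init = 0.5 * math.log(A_base / (1.0 - A_base))

    # oxygen / metabolite calibration
    f_base = Q_base / c.V_m
    O2_art = blood_o2_content(oxy.PO2_art, oxy)
    VO2_base = f_base * (O2_art - blood_o2_content(oxy.PO2c_base, oxy))
    if VO2_base <= 0:
        raise CalibrationError("arterial oxygenation below the assumed capillary level")
    D = VO2_base / (oxy.alpha * (oxy.PO2c_base - oxy.PO2t_base))
    O2t_base = tissue_o2_content(oxy.PO2t_base, oxy)
    V_max_m = VO2_base * (O2t_base + oxy.K_m_O2) / O2t_base

    plasma = 1.0 - oxy.h_t
    a_in = (f_base / oxy.v_c) * (1.0 - oxy.h_d) / plasma
    k_deg = 2.0 * oxy.k_d / (oxy.r_c * plasma)
    C_ATP0 = (a_in * oxy.C_ATP_in + oxy.h_t / plasma * atp_release(oxy.PO2c_base, oxy)) / (
        a_in + k_deg
    )
    C_ado0 = oxy.K_m_ado * oxy.F_ado_low / (oxy.V_max_ado - oxy.F_ado_low)

    return BaselineCalibration(
        K_R=K_R, K_V=K_V,
        R_p=R_p, C_p=C_p, R_v=R_v, C_v=C_v,
        P_ai=P_ai,
        r_ref=r_ref, r_base=r_base,
        P_p_base=P_p, P_a_base=P_a, P_v_base=P_v,
        Q_base=Q_base, f_base=f_base,
        A_base=A_base, x_init=x_init,
        T_0=T_0, s_sh_scale=r_base**3 / Q_base,
        C_ATP0=C_ATP0, C_ado0=C_ado0,
        V_max_m=V_max_m, D=D, O2_art=O2_art,
        PO2c_base=oxy.PO2c_base, PO2t_base=oxy.PO2t_base,
    )


RADIUS_LO, RADIUS_HI = 10e-4, 400e-4


def baseline_state(calib: BaselineCalibration) -> np.ndarray:
    """The calibrated resting state vector (an exact fixed point)."""
    return np.array([
        calib.P_p_base, calib.r_base, calib.P_v_base,
        0.0, 0.0, 0.0, 0.0,
        calib.PO2c_base, calib.PO2t_base, calib.C_ATP0, calib.C_ado0,
    ])


def make_rhs(
    subject: SubjectParams,
    calib: BaselineCalibration,
    constants: ModelConstants | None = None,
    regulation: RegulationParams | None = None,
    oxygen: OxygenParams | None = None,
    cuff_on: bool = False,
) -> Callable[[float, np.ndarray], list[float]]:
    """Compile the full right-hand side as a fast scalar closure.

    The closure inlines the circuit, regulation and metabolite equations
    (it is called hundreds of thousands of times per fit, so the generic
    per-module functions are not layered here; their agreement with this
    closure is covered by tests).  With ``cuff_on`` the end switches are
    open and the perfusion seen by the transported quantities (oxygen
    delivery, plasma ATP exchange, shear) is zero.
    """
    c = constants or ModelConstants()
    reg = regulation or RegulationParams()
    reg = replace(
        reg,
        x_init=calib.x_init,
        g_ATP=subject.g_ATP, g_ado=subject.g_ado,
        tau_ATP=subject.tau_ATP, tau_ado=subject.tau_ado,
    )
    oxy = oxygen or OxygenParams()

    # localise everything for speed
    exp, sqrt = math.exp, math.sqrt
    P_im, P_vo, V_m = c.P_im, c.P_vo, c.V_m
    r_a0, h_a0, s1, s2, ke = c.r_a0, c.h_a0, c.sigma_1, c.sigma_2, c.k_e
    Tm0, ram, rat, nm = c.T_m0, c.r_am, c.r_at, c.n_m
    wall2 = 2.0 * r_a0 * h_a0 + h_a0 * h_a0
    KR, KV, Rp, Cp, Rv, Cv, Pai = (
        calib.K_R, calib.K_V, calib.R_p, calib.C_p, calib.R_v, calib.C_v, calib.P_ai
    )
    x_init, T_0, ssh = calib.x_init, calib.T_0, calib.s_sh_scale
    CATP0, Cado0, D, Vmaxm, O2a = (
        calib.C_ATP0, calib.C_ado0, calib.D, calib.V_max_m, calib.O2_art
    )
    g_myo, g_sh, gATP, gado = reg.g_myo, reg.g_sh, reg.g_ATP, reg.g_ado
    t_myo, t_sh, tATP, tado = reg.tau_myo, reg.tau_sh, reg.tau_ATP, reg.tau_ado
    s_my, s_ATP, s_ado = reg.s_my, reg.s_ATP, reg.s_ado
    alpha, vc, vt = oxy.alpha, oxy.v_c, oxy.v_t
    CHb4, CMb, wb_a, wt_a = 4.0 * oxy.C_Hb, oxy.C_Mb, oxy.w_b * oxy.alpha, oxy.w_t * oxy.alpha
    nH, KHb, P50Mb = oxy.n_hill, oxy.P50_Hb**oxy.n_hill, oxy.P50_Mb
    KmO2, PO2cr = oxy.K_m_O2, oxy.PO2_cr
    R0, R1, CATPin = oxy.R0, oxy.R1, oxy.C_ATP_in
    plasma = 1.0 - oxy.h_t
    a_plasma = (1.0 - oxy.h_d) / plasma
    b_rel = oxy.h_t / plasma
    k_deg = 2.0 * oxy.k_d / (oxy.r_c * plasma)
    Vado, Kado = oxy.V_max_ado, oxy.K_m_ado
    Flo, Fhi, w_sw = oxy.F_ado_low, oxy.F_ado_high, oxy.ado_switch_width

    def rhs(t: float, y: np.ndarray) -> list[float]:
        Pp, r, Pv, xmy, xsh, xatp, xado, pc, pt, catp, cado = y
        z = x_init + g_myo * xmy - g_sh * xsh - gATP * xatp - gado * xado
        if z >= 0:
            A = 1.0 / (1.0 + exp(-2.0 * z))
        else:
            ez = exp(2.0 * z)
            A = ez / (1.0 + ez)
        # wall mechanics and flows
        outer = sqrt(r * r + wall2)
        Tw = (s1 * exp(ke * (r - r_a0) / r_a0) - s2) * (outer - r) \
            + A * Tm0 * exp(-abs((r - ram) / (rat - ram)) ** nm)
        Pa = (Tw + P_im * outer) / r
        Ra = KR / (r * r * r * r)
        Qa = 2.0 * (Pp - Pa) / Ra
        Qv = 2.0 * (Pa - Pv) / (Ra + Rv)
        if cuff_on:
            Qai = 0.0
            Qvo = 0.0
            f = 0.0
            ysh = -1.0
        else:
            Qai = (Pai - Pp) / Rp
            Qvo = (Pv - P_vo) / Rv
            f = Qv / V_m
            if f < 0.0:
                f = 0.0
            ysh = ssh * Qv / (r * r * r) - 1.0
        # stimuli
        ymy = s_my * (Tw - T_0)
        yatp = s_ATP * (catp - CATP0)
        yado = s_ado * (cado - Cado0)
        # oxygen
        pcc = pc if pc > 0.0 else 0.0
        ptt = pt if pt > 0.0 else 0.0
        Pn = pcc**nH
        hill = Pn / (Pn + KHb)
        o2c = CHb4 * hill + wb_a * pcc
        o2t = CMb * ptt / (ptt + P50Mb) + wt_a * ptt
        gc = CHb4 * nH * KHb * pcc ** (nH - 1.0) / (Pn + KHb) ** 2 + wb_a
        gt = CMb * P50Mb / (ptt + P50Mb) ** 2 + wt_a
        Jd = alpha * D * (pc - pt)
        VO2 = Vmaxm * o2t / (o2t + KmO2)
        Rr = R0 * (1.0 - R1 * hill)
        if w_sw > 0.0:
            u = (pt - PO2cr) / w_sw
            if u >= 0:
                sw = 1.0 / (1.0 + exp(-u))
            else:
                eu = exp(u)
                sw = eu / (1.0 + eu)
            Fado = Fhi + (Flo - Fhi) * sw
        else:
            Fado = Flo if pt >= PO2cr else Fhi
        return [
            (Qai - Qa) / Cp,
            (Qa - Qv) / (2.0 * KV * r),
            (Qv - Qvo) / Cv,
            (ymy - xmy) / t_myo,
            (ysh - xsh) / t_sh,
            (yatp - xatp) / tATP,
            (yado - xado) / tado,
            (f * (O2a - o2c) - Jd) / (vc * gc),
            (Jd - VO2) / (vt * gt),
            (f / vc) * a_plasma * (CATPin - catp) + b_rel * Rr - k_deg * catp,
            Fado - Vado * cado / (cado + Kado),
        ]

    return rhs


#: absolute tolerances per state (pressures, radius in cm, states, PO2, µM)
_ATOL = np.array([1e-7, 1e-11, 1e-7, 1e-9, 1e-9, 1e-9, 1e-9, 1e-7, 1e-7, 1e-10, 1e-10])


@dataclass
class SimulationResult:
    """A simulated cuff experiment: sampled trace plus the dense trajectory."""

    trace: PerfusionTrace
    calibration: BaselineCalibration
    subject: SubjectParams
    protocol: CuffProtocol
    _segments: list  # (t0, t1, cuff_on, OdeSolution)
    _constants: ModelConstants
    _regulation: RegulationParams

    def states(self, t: np.ndarray) -> np.ndarray:
        """Full state trajectory, shape ``(len(t), 11)`` (STATE_NAMES order)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty((t.size, len(STATE_NAMES)))
        for i, ti in enumerate(t):
            out[i] = self._segment_for(ti)(ti)
        return out

    def _segment_for(self, ti: float):
        for t0, t1, _, sol in self._segments:
            if t0 - 1e-9 <= ti <= t1 + 1e-9:
                return sol
        raise ValueError(f"time {ti:.2f} s outside the simulated range")

    def activation_at(self, t: np.ndarray) -> np.ndarray:
        """Smooth-muscle activation A(t)."""
        y = self.states(t)
        reg = self._merged_regulation()
        z = (self.calibration.x_init + reg.g_myo * y[:, 3] - reg.g_sh * y[:, 4]
             - reg.g_ATP * y[:, 5] - reg.g_ado * y[:, 6])
        return 1.0 / (1.0 + np.exp(-2.0 * np.clip(z, -300, 300)))

    def perfusion_at(self, t: np.ndarray) -> np.ndarray:
        """ASL perfusion f(t) = Q_v/V_m in mL/100g/min."""
        y = self.states(t)
        A = self.activation_at(t)
        c, calib = self._constants, self.calibration
        out = np.empty(y.shape[0])
        for i in range(y.shape[0]):
            Pa = pressure_from_radius(y[i, 1], float(A[i]), c)
            Ra, _ = arteriolar_RV(y[i, 1], calib)
            out[i] = 2.0 * (Pa - y[i, 2]) / (Ra + calib.R_v) / c.V_m * PERFUSION_SCALE
        return out

    def _merged_regulation(self) -> RegulationParams:
        return replace(
            self._regulation,
            x_init=self.calibration.x_init,
            g_ATP=self.subject.g_ATP, g_ado=self.subject.g_ado,
            tau_ATP=self.subject.tau_ATP, tau_ado=self.subject.tau_ado,
        )


def simulate(
    subject: SubjectParams,
    protocol: CuffProtocol,
    constants: ModelConstants | None = None,
    regulation: RegulationParams | None = None,
    oxygen: OxygenParams | None = None,
    rtol: float = 1e-7,
    dense: bool = True,
    t_eval: np.ndarray | None = None,
) -> SimulationResult:
    """Simulate a cuff protocol from the calibrated resting fixed point.

    Integrates the 11 coupled states through baseline → cuff → release
    with LSODA, restarting at the switch times so the solver never steps
    across a discontinuous right-hand side.  Returns the perfusion trace
    sampled on the protocol grid (``t_eval`` overrides the grid) together
    with the dense trajectory for state-level outputs.

    With ``dense=False`` only the sampled perfusion is computed (used by
    the fitting engine, which evaluates the model thousands of times).
    """
    c = constants or ModelConstants()
    calib = calibrate(subject, c, regulation, oxygen)
    y0 = baseline_state(calib)

    t_s = np.asarray(t_eval, dtype=float) if t_eval is not None else protocol.sample_times()
    segments_def = [
        (-protocol.t_baseline, 0.0, False),
        (0.0, protocol.t_cuff, True),
        (protocol.t_cuff, protocol.t_cuff + protocol.t_recovery, False),
    ]
    f_samples = np.empty(t_s.size)
    f_samples.fill(np.nan)
    segments = []
    y = y0
    for t0, t1, cuff_on in segments_def:
        rhs = make_rhs(subject, calib, c, regulation, oxygen, cuff_on=cuff_on)
        in_seg = (t_s >= t0) & (t_s < t1) if t1 < segments_def[-1][1] else (t_s >= t0) & (t_s <= t1)
        seg_t = t_s[in_seg]
        sol = solve_ivp(
            rhs, (t0, t1), y, method="LSODA",
            rtol=rtol, atol=_ATOL,
            dense_output=dense or seg_t.size > 0,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed at t={sol.t[-1]:.2f} s (state {sol.y[:, -1]!r}): "
                f"{sol.message}"
            )
        if seg_t.size:
            ys = sol.sol(seg_t)
            f_samples[in_seg] = _perfusion_from_states(ys, subject, calib, c, regulation)
        segments.append((t0, t1, cuff_on, sol.sol if sol.sol is not None else None))
        y = sol.y[:, -1]

    trace = PerfusionTrace(
        t=t_s, f=f_samples, protocol=protocol,
        meta={"source": "simulation"},
    )
    return SimulationResult(
        trace=trace, calibration=calib, subject=subject, protocol=protocol,
        _segments=segments, _constants=c, _regulation=regulation or RegulationParams(),
    )


def _perfusion_from_states(ys, subject, calib, c, regulation) -> np.ndarray:
    reg = regulation or RegulationParams()
    z = (calib.x_init + reg.g_myo * ys[3] - reg.g_sh * ys[4]
         - subject.g_ATP * ys[5] - subject.g_ado * ys[6])
    A = 1.0 / (1.0 + np.exp(-2.0 * np.clip(z, -300, 300)))
    out = np.empty(ys.shape[1])
    for i in range(ys.shape[1]):
        Pa = pressure_from_radius(float(ys[1, i]), float(A[i]), c)
        Ra = calib.K_R / float(ys[1, i]) ** 4
        out[i] = 2.0 * (Pa - ys[2, i]) / (Ra + calib.R_v) / c.V_m * PERFUSION_SCALE
    return out


def characterize(trace: PerfusionTrace) -> tuple[float, float]:
    """Peak and time-to-peak of the hyperemic response.

    The peak is the maximum perfusion sample at or after cuff release and
    TTP is its delay from the release instant; ties are broken by the
    earliest sample.  Raises ``ValueError`` when the trace has no
    post-release samples.
    """
    mask = trace.post_release_mask
    if not mask.any():
        raise ValueError("trace contains no post-release samples")
    t_post = trace.t[mask]
    f_post = trace.f[mask]
    i = int(np.argmax(f_post))  # argmax returns the first maximal sample
    return float(f_post[i]), float(t_post[i] - trace.protocol.t_cuff)
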