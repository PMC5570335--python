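"""Subject-specific parameter estimation by bounded nonlinear least squares.

Two fitting schedules are provided, mirroring how the healthy and patient
data were analysed:

* **Healthy** (multi-duration, two steps).  Step 1 frees
  ``[f_r, g_ado, tau_ado, tau_p]`` with the ATP parameters held at the
  healthy-group means and fits the long (3- and 5-min) cuff responses
  jointly; the responses to long cuffing are dominated by the slow
  adenosine arm, so the ATP parameters are not identifiable there.
  Step 2 frees ``[f_r, g_ATP, tau_ATP]`` with the step-1 adenosine/
  arterial values fixed and fits the short (1- and 2-min) responses.

* **Patient** (single 2-min trace, one step).  Frees
  ``[f_r, g_ATP, tau_ATP, R_p_scale, tau_p]`` with the adenosine
  parameters fixed to the healthy-group means; the popliteal resistance
  is free because patients have arterial stenoses.

The optimiser is trust-region-reflective bounded least squares with
multi-start (Latin-hypercube points plus the bound-centre; best final
objective wins).  Goodness of fit is the reduced chi-square against the
variance of the pre-cuff baseline samples.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .circuit import CalibrationError
from .constants import ModelConstants, OxygenParams, RegulationParams
from .simulator import (
    HEALTHY_BOUNDS,
    PATIENT_BOUNDS,
    PerfusionTrace,
    SubjectParams,
    simulate,
)

__all__ = ["FitResult", "reduced_chi_square", "fit_healthy", "fit_patient"]

#: healthy-group mean ATP parameters, fixed in step 1 and for patients' adenosine arm
GROUP_MEAN_G_ATP = 15.66
GROUP_MEAN_TAU_ATP = 15.86
GROUP_MEAN_G_ADO = 4.18
GROUP_MEAN_TAU_ADO = 43.20

#: residual magnitude returned when the model has no steady state at a
#: candidate parameter point (keeps the optimiser away from the infeasible
#: region without raising)
_INFEASIBLE_RESIDUAL = 1e3

_FIT_RTOL = 1e-6  # integration tolerance during fitting


def reduced_chi_square(
    model_f: np.ndarray,
    data_f: np.ndarray,
    sigma2: float,
    n_free: int,
) -> float:
    """Reduced chi-square ``Σ(f_model − f_data)²/σ² / (N − n − 1)``.

    ``sigma2`` is the variance of the baseline perfusion samples and
    ``n_free`` the number of free parameters.  Raises ``ValueError`` for
    degenerate inputs (``N ≤ n + 1`` or non-positive variance).
    """
    model_f = np.asarray(model_f, dtype=float)
    data_f = np.asarray(data_f, dtype=float)
    if model_f.shape != data_f.shape:
        raise ValueError("model and data series must have the same length")
    N = model_f.size
    if N <= n_free + 1:
        raise ValueError(f"need more than {n_free + 1} samples, got {N}")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return float(np.sum((model_f - data_f) ** 2) / sigma2 / (N - n_free - 1))


@dataclass
class FitResult:
    """Outcome of a subject fit."""

    params: SubjectParams
    chi2_red: float
    residuals: np.ndarray
    n_free: int
    converged: bool
    n_restarts_used: int
    objective: float
    free_names: tuple[str, ...]
    insufficient_response: bool = False
    at_bounds: tuple[str, ...] = ()
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-ready summary (used by the CLI)."""
        return {
            "params": dataclasses.asdict(self.params),
            "chi2_red": self.chi2_red,
            "n_free": self.n_free,
            "free_names": list(self.free_names),
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "objective": self.objective,
            "insufficient_response": self.insufficient_response,
            "at_bounds": list(self.at_bounds),
        }


def _model_samples(
    params: SubjectParams,
    trace: PerfusionTrace,
    constants, regulation, oxygen,
) -> np.ndarray:
    sim = simulate(
        params, trace.protocol, constants, regulation, oxygen,
        rtol=_FIT_RTOL, dense=False, t_eval=trace.t,
    )
    return sim.trace.f


def _stack_residuals(params, traces, constants, regulation, oxygen) -> np.ndarray:
    out = []
    for tr in traces:
        out.append(_model_samples(params, tr, constants, regulation, oxygen) - tr.f)
    return np.concatenate(out)


def _multistart_lsq(residual_fn, names, bounds, n_starts, seed):
    """Run bounded least squares from LHS starts plus the bound centre."""
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    starts = [0.5 * (lo + hi)]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(names), seed=seed)
        starts += [lo + s * (hi - lo) for s in sampler.random(n_starts - 1)]
    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        res = least_squares(
            residual_fn, x0, bounds=(lo, hi), method="trf",
            x_scale=(hi - lo), diff_step=1e-3,
        )
        if best is None or res.cost < best.cost:
            best = res
    at_bounds = tuple(
        n for n, x, l, h in zip(names, best.x, lo, hi)
        if x - l < 1e-8 * (h - l) or h - x < 1e-8 * (h - l)
    )
    return best, n_used, at_bounds


def _pooled_sigma2(traces: Sequence[PerfusionTrace]) -> float:
    base = np.concatenate([tr.f[tr.baseline_mask] for tr in traces])
    if base.size < 2:
        raise ValueError("traces contain fewer than two baseline samples")
    return float(np.var(base, ddof=1))


def fit_healthy(
    traces: Sequence[PerfusionTrace],
    constants: ModelConstants | None = None,
    regulation: RegulationParams | None = None,
    oxygen: OxygenParams | None = None,
    fixed_g_ATP: float = GROUP_MEAN_G_ATP,
    fixed_tau_ATP: float = GROUP_MEAN_TAU_ATP,
    n_starts: int = 6,
    seed: int = 0,
    sigma2: float | None = None,
) -> FitResult:
    """Two-step fit of a healthy subject's multi-duration responses.

    ``traces`` must include the 3- and 5-min cuff responses (step 1) and
    at least one of the 1-/2-min responses (step 2).  ``sigma2`` overrides
    the pooled baseline variance (useful for noiseless self-fits).
    """
    long_tr = [tr for tr in traces if tr.protocol.t_cuff >= 150.0]
    short_tr = [tr for tr in traces if tr.protocol.t_cuff < 150.0]
    durations = sorted(tr.protocol.t_cuff for tr in long_tr)
    if not (any(d >= 280 for d in durations) and any(150 <= d <= 200 for d in durations)):
        raise ValueError("step 1 requires both the 3- and 5-min cuff responses")
    if not short_tr:
        raise ValueError("step 2 requires at least one 1- or 2-min cuff response")

    base = SubjectParams(g_ATP=fixed_g_ATP, tau_ATP=fixed_tau_ATP)

    # --- step 1: [f_r, g_ado, tau_ado, tau_p] on the long responses
    names1 = ("f_r", "g_ado", "tau_ado", "tau_p")

    def resid1(theta):
        p = dataclasses.replace(base, **dict(zip(names1, theta)))
        try:
            return _stack_residuals(p, long_tr, constants, regulation, oxygen)
        except CalibrationError:
            n = sum(tr.t.size for tr in long_tr)
            return np.full(n, _INFEASIBLE_RESIDUAL)

    res1, used1, at1 = _multistart_lsq(resid1, names1, HEALTHY_BOUNDS, n_starts, seed)
    base = dataclasses.replace(base, **dict(zip(names1, res1.x)))

    # --- step 2: [f_r, g_ATP, tau_ATP] on the short responses
    names2 = ("f_r", "g_ATP", "tau_ATP")

    def resid2(theta):
        p = dataclasses.replace(base, **dict(zip(names2, theta)))
        try:
            return _stack_residuals(p, short_tr, constants, regulation, oxygen)
        except CalibrationError:
            n = sum(tr.t.size for tr in short_tr)
            return np.full(n, _INFEASIBLE_RESIDUAL)

    res2, used2, at2 = _multistart_lsq(resid2, names2, HEALTHY_BOUNDS, n_starts, seed + 1)
    params = dataclasses.replace(base, **dict(zip(names2, res2.x)))

    residuals = _stack_residuals(params, list(traces), constants, regulation, oxygen)
    n_free = len(names1) + len(names2) - 1  # f_r appears in both steps
    s2 = sigma2 if sigma2 is not None else _pooled_sigma2(traces)
    chi2 = reduced_chi_square(residuals, np.zeros_like(residuals), s2, n_free)
    converged = bool(res1.status > 0 and res2.status > 0)
    return FitResult(
        params=params, chi2_red=chi2, residuals=residuals, n_free=n_free,
        converged=converged, n_restarts_used=used1 + used2,
        objective=float(2.0 * res2.cost), free_names=names1 + names2,
        at_bounds=tuple(sorted(set(at1) | set(at2))),
        details={"step1_cost": float(2.0 * res1.cost), "step2_cost": float(2.0 * res2.cost)},
    )


def _response_is_sufficient(trace: PerfusionTrace, min_points: int = 4) -> bool:
    """At least ``min_points`` post-release samples two baseline SDs above baseline."""
    base = trace.f[trace.baseline_mask]
    thresh = float(np.mean(base)) + 2.0 * float(np.std(base, ddof=1))
    return int(np.sum(trace.f[trace.post_release_mask] > thresh)) >= min_points


def fit_patient(
    trace: PerfusionTrace,
    constants: ModelConstants | None = None,
    regulation: RegulationParams | None = None,
    oxygen: OxygenParams | None = None,
    fixed_g_ado: float = GROUP_MEAN_G_ADO,
    fixed_tau_ado: float = GROUP_MEAN_TAU_ADO,
    n_starts: int = 6,
    seed: int = 0,
    sigma2: float | None = None,
) -> FitResult:
    """Five-parameter fit of a single (2-min cuff) patient response.

    Flags — but still fits — responses with fewer than four post-release
    samples two baseline standard deviations above the baseline mean,
    which are too small to constrain five parameters.
    """
    names = ("f_r", "g_ATP", "tau_ATP", "R_p_scale", "tau_p")
    base = SubjectParams(g_ado=fixed_g_ado, tau_ado=fixed_tau_ado)

    def resid(theta):
        p = dataclasses.replace(base, **dict(zip(names, theta)))
        try:
            return _model_samples(p, trace, constants, regulation, oxygen) - trace.f
        except CalibrationError:
            return np.full(trace.t.size, _INFEASIBLE_RESIDUAL)

    res, used, at_b = _multistart_lsq(resid, names, PATIENT_BOUNDS, n_starts, seed)
    params = dataclasses.replace(base, **dict(zip(names, res.x)))
    s2 = sigma2 if sigma2 is not None else trace.baseline_sigma2()
    chi2 = reduced_chi_square(res.fun + trace.f, trace.f, s2, len(names))
    return FitResult(
        params=params, chi2_red=chi2, residuals=res.fun, n_free=len(names),
        converged=bool(res.status > 0), n_restarts_used=used,
        objective=float(2.0 * res.cost), free_names=names,
        insufficient_response=not _response_is_sufficient(trace),
        at_bounds=at_b,
    )
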