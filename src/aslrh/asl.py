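"""ASL difference-signal to perfusion conversion.

FAIR ASL quantification with a single post-labeling delay:

    f = λ · ΔM / (2 · TI1 · M0b · exp(−PLD/T1b))

with the blood–tissue partition coefficient λ (mL/g), bolus duration TI1
(s), post-labeling delay PLD (s), blood longitudinal relaxation time T1b
(s) and the fully relaxed blood signal M0b (arbitrary units).  Perfusion
is returned in mL/100g/min.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AslAcquisition", "signal_to_perfusion", "perfusion_to_signal"]

_TO_ML_100G_MIN = 6000.0  # (mL/g/s) -> mL/100g/min


@dataclass(frozen=True)
class AslAcquisition:
    """FAIR acquisition parameters.

    Defaults follow the 3 T protocol (TI1 = 700 ms, PLD = 1.4 s, λ = 0.9
    mL/g); T1b defaults to the standard 3 T arterial blood value.  M0b is
    scanner-dependent and must be supplied for signal conversion.
    """

    TI1: float = 0.7
    PLD: float = 1.4
    lam: float = 0.9
    T1b: float = 1.65
    M0b: float | None = None

    def __post_init__(self) -> None:
        if min(self.TI1, self.PLD, self.lam, self.T1b) <= 0:
            raise ValueError("acquisition parameters must be positive")


def signal_to_perfusion(dM: np.ndarray, acq: AslAcquisition) -> np.ndarray:
    """Convert an ASL difference-signal series ΔM(t) to perfusion.

    Returns perfusion in mL/100g/min; raises ``ValueError`` unless a
    positive ``M0b`` is set on the acquisition.
    """
    if acq.M0b is None or acq.M0b <= 0:
        raise ValueError("a positive M0b is required for signal conversion")
    dM = np.asarray(dM, dtype=float)
    f_per_s = acq.lam * dM / (2.0 * acq.TI1 * acq.M0b * np.exp(-acq.PLD / acq.T1b))
    return f_per_s * _TO_ML_100G_MIN


def perfusion_to_signal(f: np.ndarray, acq: AslAcquisition) -> np.ndarray:
    """Exact inverse of :func:`signal_to_perfusion` (f in mL/100g/min)."""
    if acq.M0b is None or acq.M0b <= 0:
        raise ValueError("a positive M0b is required for signal conversion")
    f = np.asarray(f, dtype=float) / _TO_ML_100G_MIN
    return f * (2.0 * acq.TI1 * acq.M0b * np.exp(-acq.PLD / acq.T1b)) / acq.lam
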