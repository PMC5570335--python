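"""Synthetic perfusion-trace generation.

Emulates the structure of the measured recordings: a pre-cuff baseline
segment, a gap during the occlusion (frames inside the cuff window are
absent), and a post-release hyperemic segment, all sampled at the ASL
repetition time, with additive i.i.d. Gaussian noise whose standard
deviation matches the baseline-segment noise of the recordings.  An
optional linear baseline drift mimics the slow signal drifts seen in
some acquisitions (off by default).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import ModelConstants, OxygenParams, RegulationParams
from .simulator import CuffProtocol, PerfusionTrace, SubjectParams, simulate

__all__ = ["NoiseSpec", "generate_trace"]


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic traces.

    ``sigma`` is the perfusion noise SD in mL/100g/min (default 0.5, a
    typical whole-calf ROI baseline noise level for FAIR ASL at 3 T);
    ``drift_slope`` adds a linear baseline drift in (mL/100g/min)/s.
    """

    sigma: float = 0.5
    seed: int = 0
    drift_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def generate_trace(
    subject: SubjectParams,
    protocol: CuffProtocol,
    noise: NoiseSpec,
    constants: ModelConstants | None = None,
    regulation: RegulationParams | None = None,
    oxygen: OxygenParams | None = None,
) -> PerfusionTrace:
    """Simulate a subject and corrupt the sampled trace like a recording.

    Samples inside the cuff window are dropped; reproducible for a given
    ``noise.seed``.
    """
    t = protocol.sample_times(include_cuff=False)
    sim = simulate(
        subject, protocol, constants, regulation, oxygen,
        dense=False, t_eval=t,
    )
    f = sim.trace.f.copy()
    rng = np.random.default_rng(noise.seed)
    if noise.sigma > 0:
        f = f + rng.normal(0.0, noise.sigma, f.size)
    if noise.drift_slope != 0.0:
        f = f + noise.drift_slope * (t - t[0])
    return PerfusionTrace(
        t=t, f=f, protocol=protocol,
        meta={
            "source": "synthetic",
            "sigma": noise.sigma,
            "seed": noise.seed,
            "drift_slope": noise.drift_slope,
        },
    )
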