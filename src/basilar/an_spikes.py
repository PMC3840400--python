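"""Auditory-nerve fiber discharge generator.

Spike times are drawn from a non-homogeneous Poisson process driven by the
synaptic signal s(t), thinned by refractoriness: an absolute dead time t_abs
after each spike, then a graded recovery

    R(e) = 1 - c0 exp(-(e - t_abs)/s0) - c1 exp(-(e - t_abs)/s1)

of the discharge probability with elapsed time e since the last spike.  The
per-step firing probability is s(t)·dt·R(e) (Bernoulli approximation, valid
while max(s)·dt << 1; a guard rejects max(s)·dt >= 0.1).  Trials are
independent and vectorized over a single seeded stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synapse import SynapseOutput

__all__ = ["RefractoryParams", "SpikeTrainSet", "generate_spikes"]


@dataclass
class RefractoryParams:
    """Absolute dead time and two-exponential relative refractory recovery.

    Defaults are the canonical discharge-generator values: 0.75-ms dead time
    and equal-weight recovery components with 1-ms and 12.5-ms time
    constants.
    """

    t_abs_ms: float = 0.75
    c0: float = 0.5
    s0_ms: float = 1.0
    c1: float = 0.5
    s1_ms: float = 12.5

    def __post_init__(self) -> None:
        if self.t_abs_ms <= 0:
            raise ValueError("absolute dead time must be positive")
        if self.c0 < 0 or self.c1 < 0 or self.c0 + self.c1 > 1:
            raise ValueError("need c0, c1 >= 0 and c0 + c1 <= 1")
        if not self.s0_ms < self.s1_ms:
            raise ValueError("recovery constants must satisfy s0 < s1")


@dataclass
class SpikeTrainSet:
    """Per-trial auditory-nerve spike times (ms)."""

    trials: list[np.ndarray]
    duration_ms: float
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def pooled(self) -> np.ndarray:
        if not self.trials:
            return np.empty(0)
        return np.concatenate(self.trials)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "duration_ms": self.duration_ms,
            "seed": self.seed,
            "trials": [t.tolist() for t in self.trials],
        }))

    def to_csv(self, path: str | Path) -> None:
        rows = [(i, t) for i, tr in enumerate(self.trials) for t in tr]
        pd.DataFrame(rows, columns=["trial", "spike_time_ms"]).to_csv(
            path, index=False
        )


def generate_spikes(
    s_trace: SynapseOutput | np.ndarray,
    refractory: RefractoryParams | None = RefractoryParams(),
    n_trials: int = 500,
    seed: int | None = None,
    sample_rate: float | None = None,
    rng: np.random.Generator | None = None,
) -> SpikeTrainSet:
    """Draw ``n_trials`` independent spike trains driven by s(t).

    ``s_trace`` may be a :class:`SynapseOutput` or a raw intensity array in
    spikes/s (then ``sample_rate`` is required).  Negative intensities are
    clamped to zero.  Pass ``refractory=None`` to disable refractoriness
    (pure non-homogeneous Poisson process).
    """
    if isinstance(s_trace, SynapseOutput):
        s = s_trace.clamped
        fs = s_trace.sample_rate
    else:
        if sample_rate is None:
            raise ValueError("sample_rate required for a raw intensity array")
        s = np.maximum(np.asarray(s_trace, dtype=float), 0.0)
        fs = sample_rate
    dt_s = 1.0 / fs
    dt_ms = 1e3 * dt_s
    if s.size and s.max() * dt_s >= 0.1:
        raise ValueError(
            "max(s)*dt >= 0.1: Bernoulli approximation invalid, refine the step"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    # two-stage thinning, statistically identical to per-step Bernoulli with
    # probability s*dt*R: draw candidate events at rate s(t) (vectorized),
    # then accept each with the refractory recovery R given the last
    # accepted spike (sequential over the sparse candidate list only)
    base_prob = s * dt_s
    n_steps = s.size
    duration_ms = n_steps * dt_ms
    trials: list[np.ndarray] = []
    for _ in range(n_trials):
        cand = np.flatnonzero(rng.random(n_steps) < base_prob)
        times = (cand + 0.5) * dt_ms
        if refractory is None or cand.size == 0:
            trials.append(times)
            continue
        u = rng.random(cand.size)
        t_abs, c0, s0, c1, s1 = (
            refractory.t_abs_ms, refractory.c0, refractory.s0_ms,
            refractory.c1, refractory.s1_ms,
        )
        accepted = []
        t_last = -np.inf
        for t, uu in zip(times, u):
            e = t - t_last - t_abs
            if e < 0:
                continue
            recov = 1.0 - c0 * np.exp(-e / s0) - c1 * np.exp(-e / s1)
            if uu < recov:
                accepted.append(t)
                t_last = t
        trials.append(np.asarray(accepted))
    return SpikeTrainSet(trials=trials, duration_ms=duration_ms, seed=seed)
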