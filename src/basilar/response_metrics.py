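"""Response metrics: PSTHs, onset/steady-state rates, rate-level functions,
and response areas for the simulated auditory-nerve output."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .an_spikes import SpikeTrainSet

__all__ = [
    "PSTH",
    "RateLevelCurve",
    "ResponseArea",
    "psth",
    "steady_state_rate",
    "onset_peak_rate",
    "rate_level_function",
    "response_area",
    "vector_strength",
    "iso_rate_bandwidth",
]


@dataclass
class PSTH:
    """Poststimulus time histogram pooled over trials."""

    bin_edges: np.ndarray  # ms
    counts: np.ndarray
    n_trials: int

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def rates(self) -> np.ndarray:
        """Per-bin firing rate in spikes/s."""
        return self.counts / (self.n_trials * self.bin_width_ms * 1e-3)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "bin_start_ms": self.bin_edges[:-1],
            "bin_end_ms": self.bin_edges[1:],
            "count": self.counts,
            "rate_sps": self.rates,
        }).to_csv(path, index=False)


def psth(spikes: SpikeTrainSet, bin_width_ms: float = 0.2) -> PSTH:
    """Histogram of pooled spike times with fixed-width bins from 0."""
    if bin_width_ms <= 0:
        raise ValueError("bin width must be positive")
    n_bins = max(int(np.ceil(spikes.duration_ms / bin_width_ms)), 1)
    edges = np.arange(n_bins + 1) * bin_width_ms
    counts, _ = np.histogram(spikes.pooled(), bins=edges)
    return PSTH(bin_edges=edges, counts=counts, n_trials=spikes.n_trials)


def steady_state_rate(
    spikes: SpikeTrainSet, window_ms: tuple[float, float]
) -> float:
    """Pooled firing rate (spikes/s) inside a window, from raw spike times."""
    lo, hi = window_ms
    if not hi > lo:
        raise ValueError("empty steady-state window")
    pooled = spikes.pooled()
    count = int(np.count_nonzero((pooled >= lo) & (pooled < hi)))
    return count / (spikes.n_trials * (hi - lo) * 1e-3)


def onset_peak_rate(hist: PSTH, smooth_ms: float = 1.0) -> float:
    """Maximum rate of the PSTH after moving-average smoothing."""
    rates = hist.rates
    if rates.size == 0:
        raise ValueError("empty PSTH")
    w = max(int(round(smooth_ms / hist.bin_width_ms)), 1)
    if w > 1:
        rates = np.convolve(rates, np.ones(w) / w, mode="valid")
    return float(rates.max())


def vector_strength(spikes: SpikeTrainSet, freq_hz: float) -> float:
    """Synchronization index of pooled spikes to a drive frequency."""
    pooled = spikes.pooled()
    if pooled.size == 0:
        return 0.0
    phase = 2 * np.pi * freq_hz * pooled * 1e-3
    return float(np.abs(np.exp(1j * phase).mean()))


@dataclass
class RateLevelCurve:
    spls: np.ndarray
    rates: np.ndarray
    channel: int
    freq_hz: float
    window_ms: tuple[float, float]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"spl_db": self.spls, "rate_sps": self.rates}).to_csv(
            path, index=False
        )


@dataclass
class ResponseArea:
    """Grid of steady-state rates over (frequency, level) for one channel."""

    freqs_hz: np.ndarray
    spls: np.ndarray
    rates: np.ndarray  # shape (n_freqs, n_spls)
    channel: int

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.rates, index=self.freqs_hz,
            columns=[f"{s:g}dB" for s in self.spls],
        )
        df.index.name = "freq_hz"
        df.to_csv(path)


def _default_window(duration_ms: float) -> tuple[float, float]:
    # sustained response = last half of the stimulus
    return (0.5 * duration_ms, duration_ms)


def rate_level_function(
    pipeline,
    channel: int,
    freq_hz: float,
    spls,
    n_trials: int = 500,
    seed: int | None = None,
    duration_ms: float = 50.0,
    window_ms: tuple[float, float] | None = None,
) -> RateLevelCurve:
    """Steady-state rate versus level from end-to-end simulation per SPL."""
    spls = np.asarray(spls, dtype=float)
    window = window_ms or _default_window(duration_ms)
    rates = np.empty_like(spls)
    for j, spl in enumerate(spls):
        run = pipeline.run_tone(
            channel=channel, freq_hz=freq_hz, spl=spl,
            duration_ms=duration_ms, n_trials=n_trials, seed=seed,
        )
        rates[j] = steady_state_rate(run.spikes, window)
    return RateLevelCurve(
        spls=spls, rates=rates, channel=channel, freq_hz=freq_hz,
        window_ms=window,
    )


def response_area(
    pipeline,
    channel: int,
    freqs_hz,
    spls,
    n_trials: int = 200,
    seed: int | None = None,
    duration_ms: float = 50.0,
) -> ResponseArea:
    """Steady-state rate at every (frequency, level) grid point."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    spls = np.asarray(spls, dtype=float)
    window = _default_window(duration_ms)
    rates = np.empty((freqs_hz.size, spls.size))
    for i, f in enumerate(freqs_hz):
        for j, spl in enumerate(spls):
            run = pipeline.run_tone(
                channel=channel, freq_hz=f, spl=spl,
                duration_ms=duration_ms, n_trials=n_trials, seed=seed,
            )
            rates[i, j] = steady_state_rate(run.spikes, window)
    return ResponseArea(freqs_hz=freqs_hz, spls=spls, rates=rates, channel=channel)


def iso_rate_bandwidth(area: ResponseArea, spl: float, criterion_sps: float) -> float:
    """Width (Hz) of the frequency region whose rate exceeds a criterion at
    one level, by linear interpolation at the crossings."""
    j = int(np.argmin(np.abs(area.spls - spl)))
    r = area.rates[:, j]
    f = area.freqs_hz
    above = r >= criterion_sps
    if not above.any():
        return 0.0
    i_lo, i_hi = np.flatnonzero(above)[[0, -1]]
    f_lo = f[i_lo] if i_lo == 0 else np.interp(
        criterion_sps, r[[i_lo - 1, i_lo]], f[[i_lo - 1, i_lo]]
    )
    f_hi = f[i_hi] if i_hi == f.size - 1 else np.interp(
        criterion_sps, r[[i_hi + 1, i_hi]], f[[i_hi + 1, i_hi]]
    )
    return float(f_hi - f_lo)
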