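"""Inner-hair-cell stage.

An asymmetric saturating transduction nonlinearity (opening of
mechanotransducer channels favours the excitatory direction) followed by a
single first-order membrane low-pass filter with a 1.1-kHz corner.  The
asymmetry half-wave-rectifies moderate inputs, producing a DC component that
survives the low-pass filter, while the AC component falls off with
frequency — above a few kHz essentially only the DC response remains.

Output is the deviation of intracellular potential from rest, in arbitrary
receptor-potential units (absolute calibration is not claimed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["IHCParams", "transduce", "ac_dc_profile", "measure_corner_frequency"]


@dataclass
class IHCParams:
    """Transduction parameters.

    corner_freq_khz : membrane low-pass corner (kHz).
    sat_pos, sat_neg : positive / negative saturation magnitudes of the
        memoryless map (receptor-potential units); sat_pos > sat_neg gives
        the asymmetry responsible for rectification.
    slope0 : small-signal gain at the operating point.  The pipeline feeds
        this stage in per-channel drive units (compressed signal normalized
        by the channel's response to a lower-knee-level CF tone), so the
        default gain is of order one.
    operating_point : input offset subtracted before the nonlinearity.
    """

    corner_freq_khz: float = 1.1
    sat_pos: float = 1.0
    sat_neg: float = 1.0 / 3.0
    slope0: float = 1.0
    operating_point: float = 0.0

    def __post_init__(self) -> None:
        if self.corner_freq_khz <= 0:
            raise ValueError("corner frequency must be positive")
        if not (self.sat_pos > 0 and self.sat_neg > 0):
            raise ValueError("saturation levels must be positive")
        if self.sat_pos / self.sat_neg <= 1:
            raise ValueError("asymmetry requires sat_pos > sat_neg")


def _nonlinearity(v: np.ndarray, p: IHCParams) -> np.ndarray:
    """First-order Boltzmann transducer map: value 0 and slope ``slope0`` at
    the operating point, saturating at +sat_pos / −sat_neg.

    A shifted logistic  g(v) = A / (1 + exp(−k (v − v0))) − g0  with
    A = sat_pos + sat_neg and the shift v0 set by the asymmetry ratio; being
    analytic, its harmonic series decays exponentially, which keeps the
    sampled nonlinearity free of low-frequency aliasing residue.
    """
    v = np.asarray(v, dtype=float) - p.operating_point
    amp = p.sat_pos + p.sat_neg
    k = p.slope0 * amp / (p.sat_pos * p.sat_neg)
    v0 = np.log(p.sat_pos / p.sat_neg) / k
    return amp / (1.0 + np.exp(-k * (v - v0))) - p.sat_neg


def _lowpass(x: np.ndarray, corner_hz: float, sample_rate: float) -> np.ndarray:
    # exact-pole (impulse-invariant) one-pole section: preserves the analog
    # corner at high sample rates with negligible warping
    a = np.exp(-2 * np.pi * corner_hz / sample_rate)
    return signal.lfilter([1.0 - a], [1.0, -a], x)


def transduce(x: np.ndarray, params: IHCParams, sample_rate: float) -> np.ndarray:
    """Receptor potential for a (compressed) channel signal.

    Applies the asymmetric saturating map, then the first-order membrane
    low-pass.  Accepts a 1-D trace or a channels × time matrix.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input to IHC stage")
    y = _nonlinearity(x, params)
    return _lowpass(y, params.corner_freq_khz * 1e3, sample_rate)


def _steady_ac_dc(y: np.ndarray, freq: float, sample_rate: float) -> tuple[float, float]:
    """Fundamental amplitude and mean of the steady-state tail of ``y``."""
    n_cyc = max(int(0.4 * y.size * freq / sample_rate), 2)
    n = int(round(n_cyc * sample_rate / freq))
    seg = y[-n:]
    t = np.arange(seg.size) / sample_rate
    c = np.exp(-2j * np.pi * freq * t)
    ac = 2.0 * np.abs(np.mean(seg * c))
    return float(ac), float(np.mean(seg))


def ac_dc_profile(
    params: IHCParams,
    freqs_hz: np.ndarray,
    level: float,
    sample_rate: float = 200e3,
    duration_ms: float = 60.0,
) -> np.ndarray:
    """Steady-state AC (fundamental) and DC (mean) response per tone frequency.

    Returns an array of rows (freq_hz, ac, dc) for a sinusoidal input of the
    given amplitude (input units) at each frequency.
    """
    rows = []
    n = int(round(duration_ms * 1e-3 * sample_rate))
    t = np.arange(n) / sample_rate
    for f in np.asarray(freqs_hz, dtype=float):
        if f <= 0:
            raise ValueError("frequencies must be positive")
        y = transduce(level * np.sin(2 * np.pi * f * t), params, sample_rate)
        ac, dc = _steady_ac_dc(y, f, sample_rate)
        rows.append((f, ac, dc))
    return np.array(rows)


def measure_corner_frequency(
    params: IHCParams,
    sample_rate: float = 200e3,
    ref_freq_hz: float = 50.0,
    level: float | None = None,
) -> float:
    """−3 dB frequency of the linearized stage, measured by sinusoidal sweep.

    Drives the stage with small-amplitude sinusoids (linear regime of the
    nonlinearity), takes the AC gain at ``ref_freq_hz`` as the low-frequency
    reference, and locates the 1/sqrt(2) crossing by log-log interpolation.
    """
    if level is None:
        level = 1e-3 / params.slope0  # deep inside the linear regime
    fc_nom = params.corner_freq_khz * 1e3
    freqs = np.geomspace(fc_nom / 8, fc_nom * 8, 49)
    prof = ac_dc_profile(params, np.concatenate([[ref_freq_hz], freqs]),
                         level, sample_rate, duration_ms=80.0)
    ref_ac = prof[0, 1]
    gain = prof[1:, 1] / ref_ac
    target = 1.0 / np.sqrt(2.0)
    below = np.flatnonzero(gain < target)
    if below.size == 0 or below[0] == 0:
        raise ValueError("corner not bracketed by the sweep")
    j = below[0]
    lf = np.interp(
        np.log(target), np.log(gain[[j, j - 1]]), np.log(freqs[[j, j - 1]])
    )
    return float(np.exp(lf))
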