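"""Virtual artificial basilar membrane (ABM).

A bank of 64 resonant band-pass channels stands in for the piezoelectric
membrane over a trapezoidal slit: each electrode position has a local
resonance frequency (LRF) f0 decreasing from channel 1 to channel 64, a
quality factor Q = f0 / f_bw defined through the −10 dB bandwidth of the
measured frequency response, and a relative output gain.  The bank is
calibrated through five anchor channels whose measured (f0, f_bw) pairs are
interpolated log-linearly in channel index.

Each channel is realized as a single second-order resonant band-pass filter.
For that filter |H(f)|^2 = 1 / (1 + Q_r^2 (f/f0 - f0/f)^2), so the −10 dB
width is exactly 3 f0 / Q_r and the device convention Q = f0/f_bw is
reproduced by construction with Q_r = 3 Q.

A characteristic-frequency-dependent compressive input/output stage mimics
basilar-membrane compression: growth as low as 0.2 dB/dB at high CFs between
the 40 and 90 dB SPL knees, linear growth outside them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .stimuli import AudioStimulus, pure_tone_burst, spl_to_pascal

__all__ = [
    "TABLE1_ANCHORS",
    "SlitGeometry",
    "ResonatorChannel",
    "ResonatorBank",
    "MultiChannelSignal",
    "CompressionParams",
    "build_bank",
    "lrf_theoretical",
    "fit_lrf_scale",
    "filter_stimulus",
    "frequency_response",
    "estimate_tuning",
    "compress",
    "compression_slope_for_cf",
]

#: Measured resonance anchors, channel -> (f0 kHz, f_bw kHz).
TABLE1_ANCHORS: dict[int, tuple[float, float]] = {
    2: (18.6, 2.17),
    12: (10.1, 0.820),
    34: (4.25, 0.490),
    48: (2.39, 0.407),
    62: (1.24, 0.225),
}

#: Ratio between the resonator quality Q_r and the −10 dB device Q.
QR_OVER_QDEV = 3.0


@dataclass
class SlitGeometry:
    """Trapezoidal slit under the membrane; widths in mm along the x axis."""

    short_edge_mm: float = 10.0
    long_edge_mm: float = 30.0
    axis_length_mm: float = 31.0
    membrane_thickness_um: float = 30.0

    def b_of_x(self, x_mm):
        """Local slit width (mm), linear from the short to the long edge."""
        x = np.asarray(x_mm, dtype=float)
        if np.any(x < 0) or np.any(x > self.axis_length_mm):
            raise ValueError("position outside the slit axis")
        frac = x / self.axis_length_mm
        return self.short_edge_mm + (self.long_edge_mm - self.short_edge_mm) * frac


@dataclass
class ResonatorChannel:
    index: int
    position_x_mm: float
    f0_khz: float
    q_device: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.f0_khz <= 0 or self.q_device <= 0 or self.gain <= 0:
            raise ValueError("f0, Q, and gain must all be positive")


@dataclass
class ResonatorBank:
    channels: list[ResonatorChannel]
    sample_rate: float = 200e3

    def __post_init__(self) -> None:
        f0 = self.f0_khz
        if np.any(np.diff(f0) >= 0):
            raise ValueError("channel f0 must be strictly decreasing with index")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def f0_khz(self) -> np.ndarray:
        return np.array([c.f0_khz for c in self.channels])

    def channel(self, index: int) -> ResonatorChannel:
        """Look up a channel by its 1-based device index."""
        for c in self.channels:
            if c.index == index:
                return c
        raise KeyError(f"no channel with index {index}")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "index": [c.index for c in self.channels],
                "position_x_mm": [c.position_x_mm for c in self.channels],
                "f0_kHz": [c.f0_khz for c in self.channels],
                "fbw_kHz": [c.f0_khz / c.q_device for c in self.channels],
                "q": [c.q_device for c in self.channels],
                "gain": [c.gain for c in self.channels],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, sample_rate: float = 200e3) -> "ResonatorBank":
        df = pd.read_csv(path)
        chans = [
            ResonatorChannel(
                index=int(r["index"]),
                position_x_mm=float(r["position_x_mm"]),
                f0_khz=float(r["f0_kHz"]),
                q_device=float(r["q"]),
                gain=float(r["gain"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(channels=chans, sample_rate=sample_rate)


@dataclass
class MultiChannelSignal:
    """Channels × time matrix of a processing stage."""

    values: np.ndarray
    sample_rate: float
    stage_label: str = ""
    channel_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in multichannel signal")
        if self.channel_indices is None:
            self.channel_indices = np.arange(1, self.values.shape[0] + 1)
        else:
            self.channel_indices = np.asarray(self.channel_indices, dtype=int)
            if self.channel_indices.size != self.values.shape[0]:
                raise ValueError("channel_indices length mismatch")

    def row(self, channel_index: int) -> np.ndarray:
        pos = np.flatnonzero(self.channel_indices == channel_index)
        if pos.size != 1:
            raise KeyError(f"channel {channel_index} not in signal")
        return self.values[pos[0]]

    def to_csv(self, path: str | Path) -> None:
        t_ms = np.arange(self.values.shape[1]) * 1e3 / self.sample_rate
        df = pd.DataFrame(self.values.T, columns=[f"ch{i}" for i in self.channel_indices])
        df.insert(0, "time_ms", t_ms)
        df.to_csv(path, index=False)


def _default_gain_profile(f0_khz: np.ndarray) -> np.ndarray:
    # Smooth log-normal bump: mid-frequency channels give the largest output,
    # high- and low-LRF channels less, mirroring the measured pattern.
    center_khz, width_dec = 3.2, 0.45
    return np.exp(-0.5 * ((np.log10(f0_khz) - np.log10(center_khz)) / width_dec) ** 2)


def build_bank(
    anchors: dict[int, tuple[float, float]] | None = None,
    n_channels: int = 64,
    sample_rate: float = 200e3,
    gain_profile=None,
    geometry: SlitGeometry | None = None,
) -> ResonatorBank:
    """Calibrate a resonator bank from measured anchor channels.

    ``anchors`` maps channel index to (f0 kHz, f_bw kHz).  log10(f0) and
    log10(Q) are interpolated piecewise-linearly in channel index through the
    anchors and extrapolated with the end segments, so the anchor channels
    reproduce their measured values exactly.
    """
    anchors = dict(anchors) if anchors is not None else dict(TABLE1_ANCHORS)
    if len(anchors) < 2:
        raise ValueError("need at least two anchor channels")
    idx = np.array(sorted(anchors))
    f0 = np.array([anchors[i][0] for i in idx])
    fbw = np.array([anchors[i][1] for i in idx])
    if np.any(np.diff(f0) >= 0):
        raise ValueError("anchor f0 must decrease with channel index")
    if np.any(fbw <= 0):
        raise ValueError("anchor bandwidths must be positive")
    q = f0 / fbw

    ch = np.arange(1, n_channels + 1)
    log_f0 = _interp_extrap(ch, idx, np.log10(f0))
    log_q = _interp_extrap(ch, idx, np.log10(q))
    f0_all = 10.0 ** log_f0
    q_all = 10.0 ** log_q

    geometry = geometry or SlitGeometry()
    x = (ch - 1) * geometry.axis_length_mm / max(n_channels - 1, 1)

    gains = (
        gain_profile(f0_all) if callable(gain_profile)
        else np.asarray(gain_profile, dtype=float) if gain_profile is not None
        else _default_gain_profile(f0_all)
    )
    channels = [
        ResonatorChannel(index=int(i), position_x_mm=float(xi), f0_khz=float(f),
                         q_device=float(qi), gain=float(g))
        for i, xi, f, qi, g in zip(ch, x, f0_all, q_all, gains)
    ]
    return ResonatorBank(channels=channels, sample_rate=sample_rate)


def _interp_extrap(x, xp, fp):
    """Piecewise-linear interpolation with end-segment extrapolation."""
    x = np.asarray(x, dtype=float)
    y = np.interp(x, xp, fp)
    lo, hi = x < xp[0], x > xp[-1]
    if np.any(lo):
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + slope * (x[lo] - xp[0])
    if np.any(hi):
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + slope * (x[hi] - xp[-1])
    return y


def lrf_theoretical(x_mm, geometry: SlitGeometry, scale: float):
    """Resonance frequency (kHz) of the membrane strip at position x.

    Uses the width-scaling law of a clamped strip, f0(x) = scale / b(x)^2,
    with ``scale`` in kHz·mm² fitted to measured anchors (see
    :func:`fit_lrf_scale`).
    """
    b = np.asarray(geometry.b_of_x(x_mm), dtype=float)
    if np.any(b <= 0):
        raise ValueError("slit width must be positive")
    return scale / b**2


def fit_lrf_scale(
    positions_mm: np.ndarray,
    f0_khz: np.ndarray,
    geometry: SlitGeometry | None = None,
) -> float:
    """Least-squares scale for the f0 = scale / b(x)^2 law (log-domain fit)."""
    geometry = geometry or SlitGeometry()
    b = geometry.b_of_x(np.asarray(positions_mm, dtype=float))
    # log10 f0 = log10 scale - 2 log10 b  ->  closed-form LSQ in log scale
    return float(10.0 ** np.mean(np.log10(f0_khz) + 2 * np.log10(b)))


def channel_sos(channel: ResonatorChannel, sample_rate: float) -> np.ndarray:
    """Second-order band-pass section for one channel (unit gain at f0)."""
    f0_hz = channel.f0_khz * 1e3
    if f0_hz >= sample_rate / 2:
        raise ValueError("channel resonance at or above Nyquist")
    b, a = signal.iirpeak(f0_hz, QR_OVER_QDEV * channel.q_device, fs=sample_rate)
    return signal.tf2sos(b, a)


def filter_stimulus(bank: ResonatorBank, stimulus: AudioStimulus) -> MultiChannelSignal:
    """Pass a stimulus through every channel of the bank (piezo stage, linear)."""
    if stimulus.samples.size == 0:
        raise ValueError("empty stimulus")
    if stimulus.sample_rate != bank.sample_rate:
        raise ValueError(
            "stimulus sample rate differs from bank rate; resample first"
        )
    out = np.empty((bank.n_channels, stimulus.samples.size))
    for i, chan in enumerate(bank.channels):
        sos = channel_sos(chan, bank.sample_rate)
        out[i] = chan.gain * signal.sosfilt(sos, stimulus.samples)
    return MultiChannelSignal(
        values=out,
        sample_rate=bank.sample_rate,
        stage_label="piezo",
        channel_indices=np.array([c.index for c in bank.channels]),
    )


def _steady_peak(y: np.ndarray, frac: tuple[float, float] = (0.5, 0.95)) -> float:
    n = y.size
    return float(np.max(np.abs(y[int(frac[0] * n): int(frac[1] * n)])))


def frequency_response(
    bank: ResonatorBank,
    channel: int,
    freqs_hz: np.ndarray,
    spl: float = 75.0,
    duration_ms: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulated steady-state amplitude of one channel across tone frequencies.

    For each frequency a gated tone burst is synthesized and filtered; the
    steady-state peak amplitude on the requested channel is recorded, the
    procedure used to measure the device's frequency selectivity.
    """
    chan = bank.channel(channel)
    sos = channel_sos(chan, bank.sample_rate)
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    amps = np.empty_like(freqs_hz)
    for j, f in enumerate(freqs_hz):
        tone = pure_tone_burst(f, spl, duration_ms, sample_rate=bank.sample_rate)
        y = chan.gain * signal.sosfilt(sos, tone.samples)
        amps[j] = _steady_peak(y)
    return freqs_hz, amps


@dataclass
class TuningEstimate:
    f0: float
    f_bw: float
    q: float


def estimate_tuning(freqs: np.ndarray, amps: np.ndarray) -> TuningEstimate:
    """Peak frequency, −10 dB bandwidth, and Q from a frequency-response curve.

    The peak is refined by local quadratic interpolation of the dB curve; the
    bandwidth is the distance between the two −10 dB crossings, each located
    by linear interpolation between samples.  Returned frequencies are in the
    units of ``freqs``.
    """
    freqs = np.asarray(freqs, dtype=float)
    amps = np.asarray(amps, dtype=float)
    if np.any(amps <= 0):
        raise ValueError("amplitudes must be positive")
    db = 20 * np.log10(amps)
    if np.ptp(db) < 1e-9:
        raise ValueError("flat curve: no peak")
    i = int(np.argmax(db))
    if i == 0 or i == db.size - 1:
        raise ValueError("peak at sweep edge: widen the frequency range")
    # quadratic refinement of the peak on the dB curve (local parabola)
    coef = np.polyfit(freqs[i - 1: i + 2] - freqs[i], db[i - 1: i + 2], 2)
    if coef[0] < 0:
        df = -coef[1] / (2 * coef[0])
        f_peak = freqs[i] + df
        db_peak = np.polyval(coef, df)
    else:  # degenerate curvature; fall back to the sample maximum
        f_peak, db_peak = freqs[i], db[i]

    target = db_peak - 10.0
    below_lo = np.flatnonzero(db[:i] < target)
    above_hi = np.flatnonzero(db[i:] < target)
    if below_lo.size == 0 or above_hi.size == 0:
        raise ValueError("-10 dB point not bracketed by the sweep range")
    j = below_lo[-1]
    f_lo = np.interp(target, [db[j], db[j + 1]], [freqs[j], freqs[j + 1]])
    k = i + above_hi[0]
    f_hi = np.interp(target, [db[k], db[k - 1]], [freqs[k], freqs[k - 1]])
    f_bw = f_hi - f_lo
    return TuningEstimate(f0=float(f_peak), f_bw=float(f_bw), q=float(f_peak / f_bw))


# ---------------------------------------------------------------------------
# CF-dependent compressive input/output stage


def compression_slope_for_cf(cf_khz: float) -> float:
    """Compressive growth slope (dB/dB) between the knees as a function of CF.

    0.2 dB/dB for CFs of 4 kHz and above, rising smoothly to 0.5 dB/dB at
    1 kHz and below — compression is strongest at high CFs.
    """
    lo, hi = np.log10(1.0), np.log10(4.0)
    u = np.clip((hi - np.log10(cf_khz)) / (hi - lo), 0.0, 1.0)
    smooth = u * u * (3.0 - 2.0 * u)  # smoothstep
    return float(0.2 + 0.3 * smooth)


@dataclass
class CompressionParams:
    knee_low_db: float = 40.0
    knee_high_db: float = 90.0
    slope_at_cf: float = 0.2
    smoothing_width_db: float = 2.0
    slope_vs_cf: object = compression_slope_for_cf  # CF (kHz) -> dB/dB slope

    def __post_init__(self) -> None:
        if not self.knee_low_db < self.knee_high_db:
            raise ValueError("knee_low_db must be below knee_high_db")
        if not 0 < self.slope_at_cf <= 1:
            raise ValueError("slope_at_cf must be in (0, 1]")


def _softplus(v: np.ndarray, width: float) -> np.ndarray:
    # numerically safe width*log(1+exp(v/width))
    z = v / width
    return width * (np.logaddexp(0.0, z))


def reference_amplitude(channel: ResonatorChannel, knee_low_db: float) -> float:
    """Peak piezo amplitude of the channel's response to a CF tone at the
    lower knee level: the per-channel reference that anchors the dB mapping
    of the memoryless compressor (|H(f0)| = 1 by construction)."""
    return channel.gain * np.sqrt(2.0) * spl_to_pascal(knee_low_db)


def compress(
    sig: MultiChannelSignal,
    bank: ResonatorBank,
    params: CompressionParams | None = None,
) -> MultiChannelSignal:
    """Memoryless CF-dependent compressive nonlinearity on the piezo output.

    The instantaneous magnitude is mapped through a smooth piecewise-log
    curve: unity dB/dB growth below the lower knee, the CF-dependent
    compressive slope between the knees, unity growth resumed above the upper
    knee.  Sign is preserved (odd symmetry) and the map is monotone.
    """
    params = params or CompressionParams()
    w = params.smoothing_width_db
    out = np.empty_like(sig.values)
    for i, ch_idx in enumerate(sig.channel_indices):
        chan = bank.channel(int(ch_idx))
        slope = params.slope_vs_cf(chan.f0_khz)
        a_ref = reference_amplitude(chan, params.knee_low_db)
        u = sig.values[i]
        mag = np.abs(u)
        with np.errstate(divide="ignore"):
            level = params.knee_low_db + 20.0 * np.log10(mag / a_ref)
        ramp = _softplus(level - params.knee_low_db, w) - _softplus(
            level - params.knee_high_db, w
        )
        out_level = level - (1.0 - slope) * ramp
        mapped = a_ref * 10.0 ** ((out_level - params.knee_low_db) / 20.0)
        out[i] = np.where(mag > 0, np.sign(u) * mapped, 0.0)
    return MultiChannelSignal(
        values=out,
        sample_rate=sig.sample_rate,
        stage_label="compressed",
        channel_indices=sig.channel_indices,
    )
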