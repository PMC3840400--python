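"""Calibrated acoustic and electrical stimulus synthesis.

Acoustic stimuli are sound-pressure waveforms in pascal, referenced to
20 µPa (0 dB SPL).  Tone bursts are gated with raised-cosine (Hanning-shaped)
onset/offset ramps; the steady portion is calibrated so its RMS pressure
matches the nominal sound pressure level.  Electrical stimuli are monophasic
current-pulse schedules of the kind used for intracochlear stimulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

P_REF = 20e-6  # Pa, reference pressure for 0 dB SPL

__all__ = [
    "AudioStimulus",
    "PulseTrainStimulus",
    "spl_to_pascal",
    "pascal_to_spl",
    "pure_tone_burst",
    "harmonic_complex",
    "double_pulse_train",
    "write_wav",
    "read_wav",
]


def spl_to_pascal(spl: float) -> float:
    """RMS sound pressure (Pa) for a level in dB SPL re 20 µPa."""
    return P_REF * 10.0 ** (np.asarray(spl, dtype=float) / 20.0)


def pascal_to_spl(p_rms: float) -> float:
    """Level in dB SPL re 20 µPa for an RMS pressure in Pa."""
    return 20.0 * np.log10(np.asarray(p_rms, dtype=float) / P_REF)


@dataclass
class AudioStimulus:
    """A calibrated sound-pressure waveform.

    Attributes
    ----------
    samples : ndarray
        Instantaneous sound pressure per time step, in Pa.
    sample_rate : float
        Sampling rate in Hz.
    spl_nominal : float
        Nominal level in dB SPL of the steady (post-rise, pre-fall) portion.
    description : str
        Free-text provenance.
    """

    samples: np.ndarray
    sample_rate: float
    spl_nominal: float
    description: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("stimulus samples must be finite")

    @property
    def duration_ms(self) -> float:
        return 1e3 * self.samples.size / self.sample_rate

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * (1e3 / self.sample_rate)

    def steady_slice(self, rise_fall_fraction: float = 0.01) -> slice:
        """Index slice of the steady-state portion between the gating ramps."""
        n = self.samples.size
        n_ramp = int(round(rise_fall_fraction * n))
        return slice(n_ramp, n - n_ramp if n_ramp else n)


@dataclass
class PulseTrainStimulus:
    """Schedule of monophasic current pulses for electrical stimulation."""

    amplitude_ua: float
    pulse_width_ms: float
    pulse_times_ms: np.ndarray
    polarity_pattern: np.ndarray
    ipi_ms: float | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.pulse_times_ms = np.asarray(self.pulse_times_ms, dtype=float)
        self.polarity_pattern = np.asarray(self.polarity_pattern, dtype=int)
        if self.pulse_width_ms <= 0:
            raise ValueError("pulse_width_ms must be positive")
        if np.any(np.diff(self.pulse_times_ms) <= 0):
            raise ValueError("pulse_times_ms must be strictly increasing")
        if np.any(np.diff(self.pulse_times_ms) < self.pulse_width_ms):
            raise ValueError("pulses overlap: spacing below pulse width")
        if not np.all(np.isin(self.polarity_pattern, (-1, 1))):
            raise ValueError("polarity_pattern entries must be +1 or -1")


def _gate(n: int, rise_fall_fraction: float) -> np.ndarray:
    """Raised-cosine onset/offset envelope over ``n`` samples."""
    if not 0.0 <= rise_fall_fraction < 0.5:
        raise ValueError("rise_fall_fraction must be in [0, 0.5)")
    env = np.ones(n)
    n_ramp = int(round(rise_fall_fraction * n))
    if n_ramp:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def pure_tone_burst(
    freq: float,
    spl: float,
    duration_ms: float,
    rise_fall_fraction: float = 0.01,
    sample_rate: float = 200e3,
) -> AudioStimulus:
    """Gated sinusoid at ``freq`` Hz calibrated to ``spl`` dB SPL.

    The rise/fall time defaults to 1% of the stimulus duration, with
    raised-cosine (Hanning-shaped) ramps giving a slow onset.
    """
    if freq >= sample_rate / 2:
        raise ValueError(
            f"tone frequency {freq} Hz at or above Nyquist ({sample_rate / 2} Hz)"
        )
    if freq <= 0:
        raise ValueError("tone frequency must be positive")
    n = int(round(duration_ms * 1e-3 * sample_rate))
    t = np.arange(n) / sample_rate
    amp = np.sqrt(2.0) * spl_to_pascal(spl)  # peak pressure of the sinusoid
    x = amp * np.sin(2 * np.pi * freq * t) * _gate(n, rise_fall_fraction)
    return AudioStimulus(
        samples=x,
        sample_rate=sample_rate,
        spl_nominal=spl,
        description=f"pure tone {freq:g} Hz, {spl:g} dB SPL, {duration_ms:g} ms",
    )


def harmonic_complex(
    f0: float,
    n_harmonics: int,
    spl: float,
    duration_ms: float,
    rise_fall_fraction: float = 0.01,
    sample_rate: float = 200e3,
) -> AudioStimulus:
    """Equal-amplitude cosine-phase harmonic complex at multiples of ``f0``.

    The overall level is peak-equivalent: the peak pressure of the complex
    equals the peak pressure of a sinusoid at ``spl`` dB SPL, the standard
    convention for calibrating complex stimuli by peak level.
    """
    if f0 <= 0:
        raise ValueError("fundamental frequency must be positive")
    if n_harmonics < 1:
        raise ValueError("need at least one harmonic")
    if f0 * n_harmonics >= sample_rate / 2:
        raise ValueError("top harmonic at or above Nyquist")
    n = int(round(duration_ms * 1e-3 * sample_rate))
    t = np.arange(n) / sample_rate
    peak = np.sqrt(2.0) * spl_to_pascal(spl)
    k = np.arange(1, n_harmonics + 1)[:, None]
    x = (peak / n_harmonics) * np.cos(2 * np.pi * f0 * k * t).sum(axis=0)
    x *= _gate(n, rise_fall_fraction)
    return AudioStimulus(
        samples=x,
        sample_rate=sample_rate,
        spl_nominal=spl,
        description=(
            f"harmonic complex f0={f0:g} Hz x{n_harmonics}, "
            f"peak-equivalent {spl:g} dB SPL"
        ),
    )


def double_pulse_train(
    amplitude_ua: float,
    ipi_ms: float,
    n_repeats: int,
    repeat_rate_hz: float = 50.0,
    alternate_polarity: bool = True,
    pulse_width_ms: float = 0.6,
) -> PulseTrainStimulus:
    """Double-pulse schedule: pulse pairs separated by ``ipi_ms``, repeating
    at ``repeat_rate_hz`` (50/s by default), polarity alternating per repeat
    when flagged — the alternating-polarity protocol used for artifact
    cancellation in evoked-response averaging.
    """
    if ipi_ms <= pulse_width_ms:
        raise ValueError("IPI must exceed the pulse width (pulses overlap)")
    period_ms = 1e3 / repeat_rate_hz
    if ipi_ms + pulse_width_ms > period_ms:
        raise ValueError("pulse pair does not fit in the repeat period")
    starts = np.arange(n_repeats) * period_ms
    times = np.sort(np.concatenate([starts, starts + ipi_ms]))
    if alternate_polarity:
        rep_pol = np.where(np.arange(n_repeats) % 2 == 0, 1, -1)
    else:
        rep_pol = np.ones(n_repeats, dtype=int)
    polarity = np.repeat(rep_pol, 2)
    return PulseTrainStimulus(
        amplitude_ua=amplitude_ua,
        pulse_width_ms=pulse_width_ms,
        pulse_times_ms=times,
        polarity_pattern=polarity,
        ipi_ms=ipi_ms,
        description=(
            f"double pulses, IPI {ipi_ms:g} ms, {n_repeats} repeats at "
            f"{repeat_rate_hz:g}/s"
        ),
    )


def write_wav(path: str | Path, stimulus: AudioStimulus) -> None:
    """Write a float WAV plus a JSON calibration sidecar (Pa per unit)."""
    path = Path(path)
    peak = float(np.max(np.abs(stimulus.samples))) or 1.0
    wavfile.write(path, int(stimulus.sample_rate),
                  (stimulus.samples / peak).astype(np.float32))
    sidecar = {
        "pa_per_unit": peak,
        "spl_nominal": stimulus.spl_nominal,
        "description": stimulus.description,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_wav(path: str | Path) -> AudioStimulus:
    """Read a float WAV written by :func:`write_wav` (sidecar required)."""
    path = Path(path)
    rate, data = wavfile.read(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return AudioStimulus(
        samples=np.asarray(data, dtype=float) * sidecar["pa_per_unit"],
        sample_rate=float(rate),
        spl_nominal=float(sidecar["spl_nominal"]),
        description=sidecar.get("description", ""),
    )
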