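"""IHC–auditory-nerve synapse: reservoir adaptation dynamics.

The receptor potential v(t) is mapped through a soft saturating nonlinearity
to an immediate transmitter permeability p(t).  Transmitter concentrations in
two reservoirs (an immediate store x1 that is released into the cleft at rate
p(t), and a reserve x2 exchanging with it) obey the linear time-varying
system

    dx/dt = P(t) x + p0,        s(t) = K(t) x + sigma * xi(t),

where P(t) is the rate matrix built from p(t) and the inter-reservoir
transfer rates, p0 is a constant production term that sustains spontaneous
release, and the instantaneous synaptic drive s = k_gain * p(t) * x1
(release rate, in spikes/s once scaled) optionally carries additive Gaussian
observation noise.  A step of input produces an onset overshoot followed by
a two-exponential decay: the immediate store depletes quickly (rapid
adaptation, rate growing with drive), and because the reserve is replenished
partly from the immediate store, the reserve then drains at its own
drive-independent slow rate (slow adaptation).  The transfer rates are
chosen in closed form so that the eigen-time-constants of P at the
spontaneous operating point equal the characteristic-frequency-dependent
rapid and slow adaptation time constants

    tau(CF) = a - b * log10(CF / 1 kHz),

rapid in [1, 15] ms and slow in [15, 60] ms over CF in [1, 20] kHz, both
decreasing with CF.  Integration is by classic fixed-step fourth-order
Runge–Kutta at a 5-µs step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SynapseParams",
    "SynapseOutput",
    "OnsetFit",
    "permeability",
    "tau_of_cf",
    "reservoir_rates",
    "fixed_point",
    "run_synapse",
    "fit_onset_adaptation",
    "FitError",
]


@dataclass
class SynapseParams:
    """Parameters of the permeability map and reservoir system.

    Time constants are in ms; permeabilities in 1/ms; the receptor potential
    is in the IHC stage's output units (positive saturation = 1).

    ``tau_rapid_coeffs``/``tau_slow_coeffs`` are (a, b) of
    tau = a - b*log10(CF/kHz), anchored at 10→2 ms (rapid) and 60→25 ms
    (slow) across 1→20 kHz, following the gerbil trend of CF-dependent
    adaptation.  ``spont_rate`` sets the output scale k_gain so that the
    spontaneous drive corresponds to a high-spontaneous-rate fiber.
    ``coupling_frac`` sets how strongly the reservoirs are coupled (the
    fraction of the rate gap 1/tau_r − 1/tau_s moved from the fast to the
    slow mode); it controls the relative weight of the slow adaptation
    component.

    Stability of the reservoir system for every non-negative permeability
    requires the spontaneous permeability p(0) to stay below roughly
    1/tau_rapid; the default permeability map keeps p(0) ≈ 0.018/ms, far
    under that bound across the CF range.
    """

    tau_rapid_coeffs: tuple[float, float] = (10.0, 8.0 / np.log10(20.0))
    tau_slow_coeffs: tuple[float, float] = (60.0, 35.0 / np.log10(20.0))
    tau_rapid_range: tuple[float, float] = (1.0, 15.0)
    tau_slow_range: tuple[float, float] = (15.0, 60.0)
    perm_max: float = 0.35
    perm_half: float = 0.35
    perm_slope: float = 0.12
    coupling_frac: float = 0.15
    p0: float = 1.0
    sigma: float = 0.0
    spont_rate: float = 60.0

    def __post_init__(self) -> None:
        if self.perm_max <= 0 or self.perm_slope <= 0:
            raise ValueError("permeability shape parameters must be positive")
        if self.p0 < 0 or self.sigma < 0:
            raise ValueError("p0 and sigma must be non-negative")


def permeability(v, params: SynapseParams):
    """Immediate transmitter permeability (1/ms) for receptor potential v.

    A soft saturating logistic: monotone non-decreasing, bounded by
    ``perm_max``, and strictly positive at v = 0 so that spontaneous release
    (and hence spontaneous firing) persists without stimulation.
    """
    v = np.asarray(v, dtype=float)
    out = params.perm_max / (1.0 + np.exp(-(v - params.perm_half) / params.perm_slope))
    return out if out.ndim else float(out)


def tau_of_cf(cf_khz: float, params: SynapseParams) -> tuple[float, float]:
    """Rapid and slow adaptation time constants (ms) at a given CF (kHz)."""
    if cf_khz <= 0:
        raise ValueError("CF must be positive")
    cf = float(np.clip(cf_khz, 1.0, 20.0))
    ar, br = params.tau_rapid_coeffs
    as_, bs = params.tau_slow_coeffs
    tr = float(np.clip(ar - br * np.log10(cf), *params.tau_rapid_range))
    ts = float(np.clip(as_ - bs * np.log10(cf), *params.tau_slow_range))
    return tr, ts


def reservoir_rates(cf_khz: float, params: SynapseParams):
    """Transfer rates (1/ms) of the two-reservoir system at a given CF.

    The rate matrix has the depletion/reserve structure

        P(p) = [[-(p + a),  b],
                [       c, -d]]

    with release p(t) and leak a on the immediate store x1, replenishment
    b·x2 from the reserve, re-uptake/priming flow c·x1 into the reserve, and
    total reserve relaxation d.  Writing R = 1/tau_rapid, S = 1/tau_slow,
    G = R − S and phi = ``coupling_frac``, the closed-form assignment

        p_sp + a = R − phi·G,   d = S + phi·G,   b·c = phi(1 − phi)·G²

    (with b = c = sqrt(b·c)) makes the eigenvalues of P at the spontaneous
    permeability p_sp = permeability(0) exactly −R and −S, keeps d — the
    slow rate — independent of the drive, and is stable for every p ≥ 0
    whenever p_sp < det/d ≈ 1/tau_rapid.

    Returns (a, b, c, d).
    """
    tr, ts = tau_of_cf(cf_khz, params)
    p_sp = permeability(0.0, params)
    rate_r, rate_s = 1.0 / tr, 1.0 / ts
    gap = rate_r - rate_s
    phi = params.coupling_frac
    if not 0.0 < phi < 1.0:
        raise ValueError("coupling_frac must be in (0, 1)")
    alpha = rate_r - phi * gap  # immediate-store rate at spontaneous point
    d = rate_s + phi * gap      # reserve rate, drive-independent
    bc = phi * (1.0 - phi) * gap**2
    b = c = float(np.sqrt(bc))
    a = alpha - p_sp
    if a <= 0:
        raise ValueError(
            "spontaneous permeability too large for the rapid time constant "
            "(need p(0) < (1 - coupling_frac/..)/tau_rapid)"
        )
    det0 = alpha * d - bc  # = 1/(tau_r tau_s) by construction
    if det0 - p_sp * d <= 0:
        raise ValueError("reservoir system unstable at zero permeability")
    return float(a), b, c, float(d)


def _system(cf_khz: float, params: SynapseParams):
    """Rate matrix builder A(p), constant input vector, and output gain."""
    a, b, c, d = reservoir_rates(cf_khz, params)
    p_sp = permeability(0.0, params)
    b_vec = np.array([0.0, params.p0])

    def a_of_p(p: float) -> np.ndarray:
        return np.array([[-(p + a), b], [c, -d]])

    x_sp = np.linalg.solve(a_of_p(p_sp), -b_vec)
    k_gain = params.spont_rate / (p_sp * x_sp[0])  # spikes/s per (1/ms * conc)
    return a_of_p, b_vec, k_gain, x_sp


def fixed_point(p_const: float, cf_khz: float, params: SynapseParams) -> float:
    """Steady-state drive s_ss (spikes/s) for a constant permeability input."""
    a_of_p, b_vec, k_gain, _ = _system(cf_khz, params)
    x_ss = np.linalg.solve(a_of_p(p_const), -b_vec)
    return float(k_gain * p_const * x_ss[0])


@dataclass
class SynapseOutput:
    """Instantaneous synaptic drive trace (spikes/s equivalent)."""

    s: np.ndarray
    sample_rate: float
    cf_khz: float
    noise_enabled: bool = False
    seed: int | None = None

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.s.size) * (1e3 / self.sample_rate)

    @property
    def clamped(self) -> np.ndarray:
        """Non-negative drive, the admissible intensity for spike generation."""
        return np.maximum(self.s, 0.0)


def run_synapse(
    v_trace: np.ndarray,
    cf_khz: float,
    params: SynapseParams | None = None,
    sample_rate: float = 200e3,
    seed: int | None = None,
    noise_enabled: bool = False,
) -> SynapseOutput:
    """Integrate the reservoir system for a receptor-potential trace.

    The permeability p(t) = permeability(v(t)) drives the two-reservoir
    system by classic fixed-step RK4 at the trace's sample interval (5 µs at
    the default 200-kHz rate); half-step permeabilities are linearly
    interpolated.  With ``noise_enabled`` the output carries additive
    Gaussian observation noise of intensity sigma per sample.
    """
    params = params or SynapseParams()
    v = np.asarray(v_trace, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite receptor potential input")
    dt = 1e3 / sample_rate  # ms
    if dt > 0.010 + 1e-12:
        raise ValueError("time step above 10 µs: refine the sampling")
    p = permeability(v, params)
    a_of_p, b_vec, k_gain, x_sp = _system(cf_khz, params)

    a, b, c, d = reservoir_rates(cf_khz, params)
    n = p.size
    x1 = np.empty(n)
    x2 = np.empty(n)
    x1[0], x2[0] = x_sp  # start at spontaneous steady state
    q = b_vec[1]

    def deriv(p_t, u1, u2):
        du1 = -(p_t + a) * u1 + b * u2
        du2 = c * u1 - d * u2 + q
        return du1, du2

    for i in range(n - 1):
        p0_, p1_ = p[i], p[i + 1]
        pm = 0.5 * (p0_ + p1_)
        u1, u2 = x1[i], x2[i]
        k1a, k1b = deriv(p0_, u1, u2)
        k2a, k2b = deriv(pm, u1 + 0.5 * dt * k1a, u2 + 0.5 * dt * k1b)
        k3a, k3b = deriv(pm, u1 + 0.5 * dt * k2a, u2 + 0.5 * dt * k2b)
        k4a, k4b = deriv(p1_, u1 + dt * k3a, u2 + dt * k3b)
        x1[i + 1] = u1 + dt / 6.0 * (k1a + 2 * k2a + 2 * k3a + k4a)
        x2[i + 1] = u2 + dt / 6.0 * (k1b + 2 * k2b + 2 * k3b + k4b)

    if min(x1.min(), x2.min()) < -1e-9:
        raise FloatingPointError("negative reservoir state: integration unstable")
    s = k_gain * p * x1
    if noise_enabled and params.sigma > 0:
        rng = np.random.default_rng(seed)
        s = s + params.sigma * rng.standard_normal(n)
    return SynapseOutput(
        s=s, sample_rate=sample_rate, cf_khz=cf_khz,
        noise_enabled=noise_enabled, seed=seed,
    )


class FitError(RuntimeError):
    """Raised when the onset-adaptation fit fails to converge."""


@dataclass
class OnsetFit:
    a_rapid: float
    tau_rapid: float
    a_slow: float
    tau_slow: float
    s_ss: float
    goodness: float


def fit_onset_adaptation(
    s_out: SynapseOutput,
    stim_onset_ms: float,
    stim_offset_ms: float,
    smooth_ms: float = 1.0,
) -> OnsetFit:
    """Double-exponential fit of the onset decay of the synaptic drive.

    Fits  s(t) = a_r exp(−(t−t_pk)/tau_r) + a_s exp(−(t−t_pk)/tau_s) + s_ss
    by least squares from the (smoothed) onset peak to the stimulus offset.
    The trace is first smoothed with a moving average of ``smooth_ms`` so
    that phase-locked oscillation at low CFs does not dominate the residual.
    """
    t = s_out.time_ms
    s = s_out.s.astype(float)
    if smooth_ms > 0:
        w = max(int(round(smooth_ms * 1e-3 * s_out.sample_rate)), 1)
        # cycle-synchronous boxcar: a whole number of CF periods nulls the
        # phase-locked fundamental and its harmonics instead of beating
        period = s_out.sample_rate / (s_out.cf_khz * 1e3)
        if np.isfinite(period) and period >= 2:
            k = max(int(round(w / period)), 1)
            w = max(int(round(k * period)), 1)
        s = np.convolve(s, np.ones(w) / w, mode="same")
    sel = (t >= stim_onset_ms) & (t <= stim_offset_ms)
    if not np.any(sel):
        raise ValueError("fit window empty")
    ts, ss = t[sel], s[sel]
    # decay window starts at the onset peak (searched in the first 10 ms),
    # skipping half a smoothing window where the boxcar smears the corner
    head = ts <= stim_onset_ms + 10.0
    i_pk = int(np.argmax(ss[:head.sum()]))
    skip = int(round(0.5 * smooth_ms * 1e-3 * s_out.sample_rate))
    ts, ss = ts[i_pk + skip:], ss[i_pk + skip:]
    tau = ts - ts[0]

    s_end = float(np.mean(ss[-max(ss.size // 10, 1):]))
    amp0 = max(float(ss[0] - s_end), 1e-6)

    def model(tt, a_r, tr, a_s, tsl, c):
        return a_r * np.exp(-tt / tr) + a_s * np.exp(-tt / tsl) + c

    lo = [0.0, 0.2, 0.0, 10.0, 0.0]
    hi = [np.inf, 25.0, np.inf, 300.0, np.inf]
    p_init = [0.7 * amp0, 3.0, 0.3 * amp0, 40.0, max(s_end, 1e-6)]
    p_init = np.clip(p_init, lo, hi)
    try:
        popt, _ = curve_fit(model, tau, ss, p0=p_init, bounds=(lo, hi), maxfev=20000)
    except RuntimeError as exc:
        raise FitError(
            f"onset fit did not converge (n={tau.size}, init={p_init})"
        ) from exc
    a_r, tr, a_s, tsl, c = popt
    if tr > tsl:  # keep the rapid/slow labelling canonical
        a_r, tr, a_s, tsl = a_s, tsl, a_r, tr
    resid = ss - model(tau, *popt)
    var = np.var(ss)
    goodness = 1.0 - float(np.var(resid) / var) if var > 0 else 1.0
    return OnsetFit(
        a_rapid=float(a_r), tau_rapid=float(tr), a_slow=float(a_s),
        tau_slow=float(tsl), s_ss=float(c), goodness=goodness,
    )
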