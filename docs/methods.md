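# Methods

`basilar` simulates the transformation of a calibrated sound-pressure
waveform into auditory-nerve (AN) spike trains through a cascade modeled on
a hybrid hardware system: a piezoelectric "artificial basilar membrane"
(ABM) acoustic sensor feeding a DSP implementation of inner hair cells
(IHCs), IHC–AN synapses, and AN fibers.  It also analyzes electrically
evoked auditory brainstem response (EABR) waveforms of the kind recorded
during intracochlear pulse stimulation.  This note documents the model, its
assumptions, the parameters that matter, and what the synthetic data do and
do not establish.

## Scope and assumptions

The cascade is passive and feed-forward.  There is no outer-hair-cell
active feedback, no middle/external-ear acoustics, no efferent control, and
only high-spontaneous-rate fibers are represented.  The model is therefore
meaningful for moderate-to-high levels (roughly 60–100 dB SPL) and
frequencies above ~1 kHz — the device's resonance range — and does not
reproduce tuning-curve tails, best-frequency glides, or level-dependent
tuning asymmetries.  Each of the 64 channels is independent; the local
resonance frequency (LRF) of a channel is identified with the
characteristic frequency (CF) of the AN section it drives.

## Resonator bank (ABM)

Each channel is a single second-order resonant band-pass filter.  For that
filter the squared magnitude is `1/(1 + Q_r² (f/f0 − f0/f)²)`, whose −10 dB
width is exactly `3 f0/Q_r`.  Because the device's quality factor is
defined through the −10 dB bandwidth (`Q = f0/f_bw`), setting `Q_r = 3 Q`
reproduces the measured convention by construction.  Filters are
discretized with `scipy.signal.iirpeak` (pre-warped bilinear transform); at
the 200-kHz run rate the discretization shifts the −10 dB Q by under 0.1%
for every calibrated channel.

The bank is calibrated from a five-channel anchor table of measured
(f0, f_bw) pairs — channels 2, 12, 34, 48, 62 spanning 18.6 down to
1.24 kHz.  log10(f0) and log10(Q) are interpolated piecewise-linearly in
channel index through the anchors and extrapolated with the end segments,
so anchors are reproduced exactly and f0 decreases strictly from channel 1
to 64, staying inside the 1.0–20 kHz device range.  Electrode positions are
nominal (uniform along a 31-mm axis; the printed electrode-layout
arithmetic is internally inconsistent, so positions carry no physics
downstream).  A theoretical LRF map `f0(x) = scale / b(x)²` over the
trapezoidal slit width `b(x)` (10 → 30 mm) is provided with `scale` fitted
to the anchors by log-domain least squares; it reproduces the ordering and
trend but, with only a 3× width span against a 15× frequency span, deviates
from individual anchors by up to a factor ~1.6.  The measured anchor table,
not the theory curve, calibrates the bank.

Per-channel output gains follow a smooth log-normal bump peaked near
3.2 kHz (mid-frequency channels largest), matching the qualitative measured
pattern; absolute V/Pa values are not claimed, and gains cancel out of all
downstream stages (see IHC drive units below).

## Compression

Basilar-membrane compression is a memoryless, odd-symmetric, per-channel
map applied to the resonator output.  Instantaneous magnitude is referenced
to the channel's peak response to a CF tone at the lower knee (40 dB SPL),
converted to an equivalent level L, and mapped through a smooth
piecewise-log curve: slope 1 dB/dB below the 40-dB knee, a CF-dependent
compressive slope between 40 and 90 dB, slope 1 again above.  The
compressive slope is 0.2 dB/dB for CFs ≥ 4 kHz, rising smoothly
(smoothstep in log CF) to 0.5 dB/dB at 1 kHz, reflecting weaker compression
at low CFs.  Knee transitions are blended with a 2-dB softplus so the
mid-region slope is attained to ~1e-4 between 55 and 75 dB.

## Inner hair cell

Transduction is a first-order Boltzmann (shifted logistic) map with
positive/negative saturations 1 : 1/3 and unit small-signal slope, followed
by a single first-order low-pass at 1.1 kHz (exact-pole discretization, so
the −3 dB point is preserved to ~0.01% at 200 kHz).  The Boltzmann form was
chosen over piecewise-exponential saturation deliberately: being analytic,
its harmonic series decays exponentially, so the sampled nonlinearity does
not alias high harmonics of high-CF tones into the low-frequency band where
they would masquerade as adaptation components.  The asymmetry produces the
half-wave-rectified DC component that survives the low-pass; the AC
component falls with frequency so that above a few kHz the response is
mostly DC.

The IHC stage operates in per-channel drive units: the compressed signal is
normalized by the channel's reference response (its 40-dB CF-tone peak).
This realizes the multichannel DSP's independent per-section parameter sets
with a single dimensionless operating range and removes the arbitrary piezo
gain scale from the neural stages.

## IHC–AN synapse

The receptor potential v is mapped to an immediate transmitter
permeability p(v): a logistic saturating at `perm_max = 0.35 /ms` with
half-point 0.35 and slope 0.12 in IHC units, positive at rest
(p(0) ≈ 0.018 /ms) so spontaneous release persists.  Two transmitter
reservoirs — an immediate store x1 released into the cleft at rate p(t),
and a reserve x2 — obey

    dx/dt = P(t) x + p0,    s(t) = k_gain · p(t) · x1 (+ σ·noise),

with the Metzler rate matrix

    P(p) = [ −(p + a)   b ]
           [      c    −d ].

Given the CF-dependent rapid and slow adaptation time constants
`τ = A − B·log10(CF/kHz)` (rapid 10 → 2 ms and slow 60 → 25 ms across
1 → 20 kHz, clamped to [1, 15] and [15, 60] ms — the published
physiological ranges, with the log-CF trend reported for gerbil
primary-like fibers), the rates (a, b, c, d) are assigned in closed form so
that the eigenvalues of P at the spontaneous operating point are exactly
−1/τ_rapid and −1/τ_slow.  Writing R = 1/τ_r, S = 1/τ_s, G = R − S and a
coupling fraction φ = 0.15:

    p_sp + a = R − φG,    d = S + φG,    b = c = √(φ(1−φ)) · G.

The structure matters: d — the reserve's relaxation rate — is independent
of the drive, so the slow adaptation component survives during
stimulation (the reserve drains only because its replenishment c·x1 falls
as the immediate store depletes), while the fast rate p + a grows with
drive, as rapid adaptation should.  φ sets the relative weight of the slow
component (fraction bc/(bc+R·S·τ_rτ_s⁻¹·…) ≈ 0.3–0.4 of the reserve's
steady inflow).  The system is stable and componentwise non-negative for
every p ≥ 0 provided p(0) < det(P)/d ≈ 1/τ_rapid, which the default
permeability floor satisfies by an order of magnitude.  The production term
p0 enters the reserve only; the output gain k_gain is set in closed form so
the spontaneous drive equals 60 spikes/s, a high-spontaneous-rate fiber
(free parameters here are calibrated to published response ranges, the same
procedure the original hardware model used where direct measurements were
unavailable).

Integration is classic fixed-step fourth-order Runge–Kutta at the 5-µs
sample interval, with half-step permeabilities linearly interpolated;
halving the step changes the output by < 0.1% RMS.  Observation noise
σ·ξ(t) (unit-variance Gaussian per sample) is off by default and never
enters the state.

Onset adaptation is quantified by least-squares fitting
`s(t) = a_r e^(−t/τ_r) + a_s e^(−t/τ_s) + s_ss` from the onset peak to the
stimulus offset.  Before fitting, the trace is smoothed with a
cycle-synchronous boxcar (a whole number of CF periods, nominally 1 ms)
that nulls the phase-locked fundamental and its harmonics; the first half
smoothing-window after the peak is skipped because the boxcar smears the
corner there.  With 50-ms CF bursts at 80 dB SPL the fitted rapid constants
on the five anchor channels fall between 3 and 4 ms — shorter than the
spontaneous-point eigenvalues because depletion accelerates under drive,
and within the 1–15 ms physiological range.

## AN discharge generator

Spikes are drawn from a non-homogeneous Poisson process with intensity
max(s, 0), thinned by refractoriness: absolute dead time t_abs = 0.75 ms,
then recovery `R(e) = 1 − c0 e^(−(e−t_abs)/s0) − c1 e^(−(e−t_abs)/s1)` with
c0 = c1 = 0.5, s0 = 1 ms, s1 = 12.5 ms — the canonical discharge-generator
constants.  The per-step Bernoulli probability s·dt·R is implemented as
exact two-stage thinning (vectorized candidate draws at rate s, then
sequential refractory acceptance), which is statistically identical and
fast; a guard rejects s·dt ≥ 0.1 where the Bernoulli approximation would
degrade.  With constant drive and dead time only, the mean rate matches the
renewal closed form s/(1 + s·t_abs) within sampling error; with
refractoriness disabled the ISI distribution is exponential.  One RNG
stream per channel is derived by `SeedSequence(seed).spawn(64)`, so any
channel subset reproduces bit-identically regardless of which other
channels are simulated.

## Response metrics

PSTHs use 0.2-ms bins pooled over trials (500 by default).  Steady-state
rates are computed from raw spike times over the last half of the stimulus
("sustained response"); onset peak rates are the maximum of the
rate-converted PSTH after 1-ms moving-average smoothing.  Rate-level
functions and response areas re-run the full cascade per (frequency,
level).  Phase locking is summarized by vector strength of pooled spike
phases.

## EABR analysis

Averaged evoked potentials are processed as recorded: equal numbers of
positive- and negative-polarity trials are averaged (the polarity-following
electrical artifact cancels exactly; the polarity-invariant neural wave
remains), band-pass filtered 200–1000 Hz with a zero-phase second-order
Butterworth (zero-phase to preserve peak latencies), and the P1/N1/P2/N2
deflections extracted as window extrema (defaults 0.5–2, 1–3, 2–5, 3–7 ms
post-pulse) referenced to the mean of a 2-ms prestimulus baseline.  Results
are flagged low-confidence when an extremum sits on a window edge or below
3× the prestimulus noise SD.  Growth functions are ordinary least-squares
lines of P1−N1 against pulse current; double-pulse suppression reports the
second/first P1−N1 ratio per interpulse interval (IPI), measuring only the
P1/N1 windows so intervals down to the end of the N1 window are separable.

The synthetic generator emulates this morphology for testing: each pulse
contributes a causally gated Gabor complex (520-Hz oscillation, 1.4-ms
Gaussian envelope) whose alternating extrema sit at ~1.0 / 2.0 / 2.9 /
3.8 ms; second pulses are scaled by `1 − e^(−IPI/τ_rec)` (default
τ_rec = 2.5 ms, giving near-full recovery above ~10 ms and clear
suppression below ~7 ms); a rectangular polarity-following artifact and
white noise are added per trial.  The oscillation frequency sits mid-band,
so the analysis band-pass distorts P1−N1 by under 4% — as for a real EABR,
which is itself recorded through this band-pass.  The generator is a test
fixture for the analysis code, not a physiological claim: the animal
results it imitates (growth slopes, the near-constant N1, exact suppression
boundaries) are experimental facts the package does not attempt to
reproduce.

## What the synthetic tests do and do not show

The acceptance-grade checks establish that the implementation reproduces
its own calibration (the anchor tuning table, the 1.1-kHz corner, the
0.2-dB/dB compressive slope, physiological adaptation constants) and the
model-structural properties (linearity, tonotopy, renewal statistics,
resolved-vs-unresolved harmonic place coding, artifact-cancellation
algebra).  They do not validate the model against animal data: real AN
fibers have tails, glides, level-dependent tuning, and spontaneous-rate
diversity that this passive cascade omits by design.

## Numerical choices and degenerate inputs

Sample rate 200 kHz; solver step tied to it (5 µs) and capped at 10 µs.
Frequency-response sweeps use 50-ms bursts with a 1% raised-cosine
rise/fall and read the steady-state peak from the 50–95% window (several
ring-up times even for the narrowest resonator); tuning estimation refines
the peak with a local parabola on the dB curve and locates −10 dB crossings
by linear interpolation, raising errors for flat curves, edge peaks, or
unbracketed crossings.  Compression maps zero samples to zero exactly.
The onset fit raises a diagnostic error if the optimizer fails; a constant
trace fits with near-zero transient amplitudes.  Empty spike sets histogram
to zeros; empty analysis windows are errors.
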