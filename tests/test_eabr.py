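import numpy as np
import pytest

from basilar import eabr, stimuli
from basilar.eabr import (
    DEFAULT_TEMPLATE,
    EABRWaveform,
    PeakTemplate,
    alternating_average,
    bandpass,
    growth_function,
    ipi_suppression,
    pick_peaks,
    synth_eabr,
)

FS = 25e3


def gaussian_wave(peaks, n_ms=12.0, prestim=2.0, noise=0.0, seed=0):
    """Waveform from explicit (latency, amplitude, width) deflections."""
    n = int(n_ms * 1e-3 * FS)
    t = np.arange(n) * 1e3 / FS - prestim
    x = np.zeros(n)
    for lat, amp, w in peaks:
        x += amp * np.exp(-0.5 * ((t - lat) / w) ** 2)
    if noise:
        x = x + noise * np.random.default_rng(seed).standard_normal(n)
    return EABRWaveform(x, FS, prestim_ms=prestim)


class TestAlternatingAverage:
    def test_polarity_following_artifact_cancels(self):
        rng = np.random.default_rng(0)
        neural = rng.standard_normal(200)
        artifact = 1e4 * np.sin(np.arange(200))
        pos = np.tile(neural + artifact, (10, 1))
        neg = np.tile(neural - artifact, (10, 1))
        avg = alternating_average(pos, neg)
        np.testing.assert_allclose(avg.samples_uv, neural, atol=1e-9 * 1e4)

    def test_identity_on_identical_trials(self):
        w = np.sin(np.linspace(0, 3, 100))
        avg = alternating_average(np.tile(w, (4, 1)), np.tile(w, (4, 1)))
        np.testing.assert_allclose(avg.samples_uv, w, atol=1e-14)

    def test_noise_reduction_scales_with_trial_count(self):
        rng = np.random.default_rng(1)
        pos = rng.standard_normal((500, 400))
        neg = rng.standard_normal((500, 400))
        avg = alternating_average(pos, neg)
        resid = np.std(avg.samples_uv)
        assert resid == pytest.approx(1.0 / np.sqrt(1000), rel=0.25)

    def test_mismatched_blocks_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            alternating_average(np.zeros((3, 10)), np.zeros((4, 10)))


class TestBandpass:
    def make(self, x):
        return EABRWaveform(x, FS, prestim_ms=0.0)

    def test_in_band_tone_passes_near_unity(self):
        t = np.arange(int(0.2 * FS)) / FS
        w = bandpass(self.make(np.sin(2 * np.pi * 600 * t)))
        gain = np.max(np.abs(w.samples_uv[1000:-1000]))
        assert abs(20 * np.log10(gain)) < 1.0

    def test_dc_removed(self):
        w = bandpass(self.make(np.full(5000, 7.3)))
        assert abs(np.mean(w.samples_uv[1000:-1000])) < 1e-3

    def test_mains_frequency_attenuated(self):
        t = np.arange(int(0.5 * FS)) / FS
        w = bandpass(self.make(np.sin(2 * np.pi * 50 * t)))
        gain = np.max(np.abs(w.samples_uv[2000:-2000]))
        assert 20 * np.log10(gain) < -20.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            bandpass(self.make(np.zeros(100)), 1000.0, 200.0)


class TestPickPeaks:
    def test_constructed_peaks_recovered(self):
        wave = gaussian_wave([(1.0, 2.0, 0.15), (1.8, -1.0, 0.15)])
        pk = pick_peaks(wave)
        assert pk.p1.latency_ms == pytest.approx(1.0, abs=1e3 / FS)
        assert pk.n1.latency_ms == pytest.approx(1.8, abs=1e3 / FS)
        assert pk.p1n1 == pytest.approx(3.0, rel=0.01)

    def test_baseline_referenced_offset_invariance(self):
        wave = gaussian_wave([(1.0, 2.0, 0.15), (1.8, -1.0, 0.15)])
        shifted = EABRWaveform(wave.samples_uv + 11.0, FS, prestim_ms=2.0)
        assert pick_peaks(shifted).p1n1 == pytest.approx(pick_peaks(wave).p1n1, rel=1e-9)

    def test_pure_noise_flagged_low_confidence(self):
        wave = gaussian_wave([], noise=1.0, seed=3)
        assert not pick_peaks(wave).confident

    def test_latency_ordering(self):
        ref = DEFAULT_TEMPLATE.reference_peaks(FS)
        assert ref.p1.latency_ms < ref.n1.latency_ms < ref.p2.latency_ms < ref.n2.latency_ms


class TestGrowthFunction:
    def test_noiseless_line_recovered_exactly(self):
        levels = np.array([100.0, 200.0, 300.0, 400.0])
        amps = 0.02 * levels + 1.0  # 2 µV per 100 µA
        slope, intercept, r2 = growth_function(levels, amps)
        assert slope == pytest.approx(0.02, rel=1e-12)
        assert intercept == pytest.approx(1.0, rel=1e-9)
        assert r2 > 0.99

    def test_symmetric_noise_leaves_slope_unbiased(self):
        rng = np.random.default_rng(7)
        levels = np.array([100.0, 200.0, 300.0, 400.0, 500.0])
        slopes = []
        for _ in range(100):
            amps = 0.02 * levels + rng.standard_normal(5) * 0.3
            slopes.append(growth_function(levels, amps)[0])
        assert np.mean(slopes) == pytest.approx(0.02, rel=0.02)

    def test_constant_amplitude_gives_zero_slope(self):
        slope, _, _ = growth_function([100.0, 200.0, 300.0], [2.0, 2.0, 2.0])
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            growth_function([100.0, 200.0], [1.0, 2.0])


class TestSynthAndSuppression:
    def test_noiseless_artifact_free_average_is_template(self):
        stim = stimuli.double_pulse_train(300.0, 13.0, n_repeats=2)
        pos, neg = synth_eabr(stim, noise_sd_uv=0.0, artifact_amp_uv=0.0, seed=0)
        avg = alternating_average(pos, neg, stimulus=stim)
        expected = DEFAULT_TEMPLATE.complex_at(avg.time_ms, 0.0)
        expected += DEFAULT_TEMPLATE.complex_at(
            avg.time_ms, 13.0, 1.0 - np.exp(-13.0 / 2.5)
        )
        np.testing.assert_allclose(avg.samples_uv, expected, atol=1e-12)

    def test_seed_reproducibility(self):
        stim = stimuli.double_pulse_train(300.0, 7.0, n_repeats=2)
        a = synth_eabr(stim, seed=5)
        b = synth_eabr(stim, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_fifty_percent_suppression_recovered(self):
        # narrow, well-separated complexes; recovery tau set for a 0.5
        # second/first ratio at a 3-ms interval
        template = PeakTemplate(sigma_ms=0.45, center_ms=1.3)
        tau = 3.0 / np.log(2.0)
        stim = stimuli.double_pulse_train(300.0, 3.0, n_repeats=2)
        pos, neg = synth_eabr(stim, template=template, noise_sd_uv=0.0,
                              recovery_tau_ms=tau, seed=1)
        wave = alternating_average(pos, neg, stimulus=stim)
        curve = ipi_suppression({3.0: wave})
        assert curve[0, 1] == pytest.approx(0.5, rel=0.02)

    def test_full_recovery_at_long_interval(self):
        stim = stimuli.double_pulse_train(300.0, 13.0, n_repeats=2)
        pos, neg = synth_eabr(stim, noise_sd_uv=0.2, seed=2)
        wave = bandpass(alternating_average(pos, neg, stimulus=stim))
        curve = ipi_suppression({13.0: wave})
        assert curve[0, 1] == pytest.approx(1.0, abs=0.05)

    def test_ratio_monotone_in_interval(self):
        waves = {}
        for ipi in (3.0, 5.0, 7.0, 10.0, 13.0):
            stim = stimuli.double_pulse_train(300.0, ipi, n_repeats=2)
            pos, neg = synth_eabr(stim, noise_sd_uv=0.0, seed=3)
            waves[ipi] = alternating_average(pos, neg, stimulus=stim)
        curve = ipi_suppression(waves)
        assert np.all(np.diff(curve[:, 1]) > 0)

    def test_unseparable_interval_rejected(self):
        stim = stimuli.double_pulse_train(300.0, 2.0, n_repeats=2)
        pos, neg = synth_eabr(stim, noise_sd_uv=0.0, seed=4)
        wave = alternating_average(pos, neg, stimulus=stim)
        with pytest.raises(ValueError, match="separable"):
            ipi_suppression({2.0: wave})


class TestEndToEndRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_synthetic_recovery_through_full_chain(self, seed):
        stim = stimuli.double_pulse_train(300.0, 13.0, n_repeats=2)
        ref = DEFAULT_TEMPLATE.reference_peaks(FS)
        pos, neg = synth_eabr(stim, noise_sd_uv=1.0, seed=seed)
        wave = bandpass(alternating_average(pos, neg, stimulus=stim))
        pk = pick_peaks(wave)
        for name in ("p1", "n1", "p2", "n2"):
            got = getattr(pk, name).latency_ms
            want = getattr(ref, name).latency_ms
            assert abs(got - want) <= 1e3 / FS + 1e-9
        assert pk.p1n1 == pytest.approx(ref.p1n1, rel=0.05)

    def test_artifact_residual_power(self):
        stim = stimuli.double_pulse_train(300.0, 13.0, n_repeats=2)
        pos, neg = synth_eabr(stim, noise_sd_uv=0.0, artifact_amp_uv=100.0, seed=0)
        pure_pos, pure_neg = synth_eabr(stim, noise_sd_uv=0.0,
                                        artifact_amp_uv=0.0, seed=0)
        avg = alternating_average(pos, neg)
        neural = alternating_average(pure_pos, pure_neg)
        artifact_single = pos.mean(axis=0) - neural.samples_uv
        resid = np.sum((avg.samples_uv - neural.samples_uv) ** 2)
        assert resid < 1e-6 * np.sum(artifact_single**2)

    def test_csv_round_trip(self, tmp_path):
        stim = stimuli.double_pulse_train(300.0, 13.0, n_repeats=2)
        pos, neg = synth_eabr(stim, seed=0)
        wave = alternating_average(pos, neg, stimulus=stim)
        wave.to_csv(tmp_path / "eabr.csv")
        back = EABRWaveform.from_csv(tmp_path / "eabr.csv")
        np.testing.assert_allclose(back.samples_uv, wave.samples_uv, atol=1e-9)
        assert back.sample_rate == pytest.approx(FS, rel=1e-6)
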