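"""Detector components: filtering, denoising, detection, measurement, scoring."""
import numpy as np
import pytest
from scipy import signal

from minifract.detect import (
    DetectionConfig,
    _SwtBank,
    detect_events,
    highpass_baseline,
    measure_mini,
    score_detection,
    wavelet_denoise,
)
from minifract.synth import (
    KineticsDistributions,
    MiniKinetics,
    mini_waveform,
    synth_recording,
)

FS = 20000.0


def _trace_with_minis(onsets, amps=11.6, tr=3.2, td=36.3, dur=4.0, noise=0.0, seed=0):
    n = int(dur * FS)
    x = np.zeros(n)
    amps = np.broadcast_to(amps, (len(onsets),))
    for o, a in zip(onsets, amps):
        k = mini_waveform(MiniKinetics(a, tr, td), FS)
        i = int(round(o * FS))
        m = min(k.size, n - i)
        x[i : i + m] += k[:m]
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, n)
    return x


class TestHighpass:
    def test_dc_rejection(self):
        x = np.full(int(2 * FS), 25.0)
        y = highpass_baseline(x)
        assert np.abs(y).max() < 25.0 * 1e-6

    def test_passband_sinusoid_preserved(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 100 * t)
        y = highpass_baseline(x)
        mid = slice(int(FS), int(3 * FS))
        amp = np.sqrt(2) * y[mid].std()
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_stopband_sinusoid_attenuated(self):
        t = np.arange(int(40 * FS)) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        y = highpass_baseline(x)
        mid = slice(int(15 * FS), int(25 * FS))
        # an 8th-order corner at 2 Hz leaves < 1% at 0.1 Hz (> 40 dB down)
        assert np.abs(y[mid]).max() < 0.01

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            highpass_baseline(np.zeros(10))


class TestSwtBank:
    def test_kernels_reproduce_reference_transform(self):
        """FIR band kernels match pywt's stationary transform exactly."""
        import pywt

        rng = np.random.default_rng(0)
        x = rng.normal(size=1024)
        bank = _SwtBank.get("rbio2.2", 5)
        import warnings as w

        with w.catch_warnings():
            w.simplefilter("ignore")
            ref = pywt.swt(x, "rbio2.2", level=5, trim_approx=True, norm=True)
        for band in range(6):
            got = bank.analyze(x, band)
            inner = slice(200, 824)  # away from boundary handling differences
            np.testing.assert_allclose(got[inner], ref[band][inner], atol=1e-10)

    def test_round_trip_reconstruction(self):
        """Summing all synthesis bands inverts the analysis exactly."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=2048)
        bank = _SwtBank.get("rbio2.2", 5)
        rec = np.zeros_like(x)
        for band in range(6):
            rec += bank.synthesize(bank.analyze(x, band), band)
        inner = slice(300, 1748)
        np.testing.assert_allclose(rec[inner], x[inner], atol=1e-8)

    def test_unknown_wavelet_lists_alternatives(self):
        with pytest.raises(ValueError, match="rbio"):
            _SwtBank.get("nosuchwavelet9.9", 5)


class TestWaveletDenoise:
    def test_zero_trace_stays_zero(self):
        out = wavelet_denoise(np.zeros(4096))
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_pure_noise_is_silenced(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 3.87, int(10 * FS))
        out = wavelet_denoise(x)
        # soft thresholding at >4 sigma silences all but rare excursions
        assert np.mean(out != 0) < 1e-3
        assert np.abs(out).max() < 3.0

    def test_mini_survives_denoising(self):
        x = _trace_with_minis([1.0], noise=11.6 / 3, seed=3)
        out = wavelet_denoise(x)
        i = int(1.0 * FS)
        assert out[i : i + 400].min() < -5.0


class TestDetectEvents:
    def test_silent_trace_yields_nothing(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 3.87, int(20 * FS))
        hp = highpass_baseline(x)
        assert detect_events(hp).size == 0

    def test_single_clean_mini_located_precisely(self):
        x = _trace_with_minis([1.5], noise=0.5, seed=5)
        st = detect_events(highpass_baseline(x))
        assert st.size == 1
        assert abs(st[0] - 1.5) < 0.6e-3

    def test_two_separated_minis(self):
        x = _trace_with_minis([1.0, 1.05], noise=0.5, seed=6)
        st = detect_events(highpass_baseline(x))
        assert st.size == 2
        assert abs(st[0] - 1.0) < 0.6e-3 and abs(st[1] - 1.05) < 0.6e-3

    def test_threshold_monotonicity(self):
        """A more negative detection threshold never adds detections."""
        rng = np.random.default_rng(7)
        rec = synth_recording(2.0, 30, 3.0, KineticsDistributions(), rng)
        hp = highpass_baseline(rec.samples)
        counts = []
        for thr in (-1.0, -3.0, -6.0, -12.0):
            counts.append(detect_events(hp, DetectionConfig(detect_threshold=thr)).size)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_translation_equivariance(self):
        """Shifting the trace by k samples shifts every start by k/fs."""
        x = _trace_with_minis([0.8, 1.3], noise=11.6 / 3, dur=3.0, seed=8)
        hp = highpass_baseline(x)
        k = 160
        shifted = np.concatenate([hp[-k:], hp[:-k]])
        # padding at the trace boundary breaks exact invariance there;
        # compare detections in the interior
        a = detect_events(hp)
        b = detect_events(shifted)
        a = a[(a > 0.3) & (a < 2.6)]
        b = b[(b > 0.3) & (b < 2.6)]
        assert a.size == b.size
        np.testing.assert_allclose(b, a + k / FS, atol=2.5e-5)


class TestMeasureMini:
    def test_parameter_recovery_on_clean_kernel(self):
        x = _trace_with_minis([0.5], amps=10.0, tr=3.0, td=36.0, dur=1.5)
        m = measure_mini(x, 0.5)
        assert m.amplitude == pytest.approx(-10.0, rel=0.02)
        assert m.tau_rise == pytest.approx(3.0, rel=0.05)
        assert m.tau_decay == pytest.approx(36.0, rel=0.05)
        assert m.amplitude < 0 and m.peak_time > m.start_time

    def test_flat_trace_has_no_event(self):
        with pytest.raises(ValueError, match="minimum"):
            measure_mini(np.zeros(4000), 0.05)

    def test_noisy_amplitude_error_distribution(self):
        errs = []
        for seed in range(50):
            x = _trace_with_minis(
                [0.5], amps=11.6, dur=1.2, noise=11.6 / 3, seed=seed
            )
            m = measure_mini(x, 0.5)
            errs.append(abs(m.amplitude + 11.6) / 11.6)
        assert np.median(errs) < 0.10


class TestScoreDetection:
    def test_perfect_detection(self):
        t = np.array([1.0, 2.0, 3.0])
        s = score_detection(t, t, record_duration=4.0)
        assert s.true_positive_rate == 1.0 and s.false_positive_rate == 0.0

    def test_shift_beyond_tolerance_matches_nothing(self):
        t = np.array([1.0, 2.0, 3.0])
        s = score_detection(t + 1e-3, t, record_duration=4.0)
        assert s.true_positive_rate == 0.0

    def test_empty_detections(self):
        s = score_detection(np.array([]), np.array([1.0]), record_duration=2.0)
        assert s.true_positive_rate == 0.0 and s.false_positive_rate == 0.0

    def test_one_to_one_uses_each_side_once(self):
        truth = np.array([1.0, 1.0004])
        det = np.array([1.0001])
        s = score_detection(det, truth, record_duration=2.0)
        assert s.n_matched == 1

    def test_tolerance_matching_credits_merged_pairs(self):
        truth = np.array([1.0, 1.0004])
        det = np.array([1.0001])
        s = score_detection(det, truth, record_duration=2.0, matching="tolerance")
        assert s.n_matched == 2
        assert s.false_positive_rate == 0.0

    def test_unknown_matching_mode_rejected(self):
        with pytest.raises(ValueError, match="matching"):
            score_detection(np.array([1.0]), np.array([1.0]), matching="fuzzy")
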