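import numpy as np
import pytest

from ecgstack.dataio import BeatAnnotation, EcgSignal
from ecgstack.preprocess import (BEAT_LEN, POST_R, PRE_R, DenoiseConfig,
                                 denoise, segment_beats, wavelet_transform)
from ecgstack.synth import SynthEcgConfig, synth_ecg


def _ricker_direct(x, scales):
    """Independent direct-summation oracle for the scale-time transform."""
    def psi(t):
        return (2.0 / (np.sqrt(3.0) * np.pi**0.25)) * (1 - t**2) * np.exp(-t**2 / 2)

    n = len(x)
    out = np.zeros((len(scales), n))
    for i, m in enumerate(scales):
        for tau in range(n):
            t = np.arange(n)
            out[i, tau] = m**-0.5 * np.sum(x * psi((t - tau) / m))
    return out


class TestWaveletTransform:
    def test_zero_signal(self):
        sig = EcgSignal(samples=np.zeros(200) + 0.0, fs=360)
        out = wavelet_transform(sig, [1, 4, 16])
        assert out.shape == (3, 200)
        np.testing.assert_array_equal(out, 0.0)

    def test_impulse_matches_direct_summation(self):
        x = np.zeros(101)
        x[50] = 1.0
        sig = EcgSignal(samples=x, fs=360)
        for m in (2.0, 5.0):
            row = wavelet_transform(sig, [m])[0]
            expected = _ricker_direct(x, [m])[0]
            np.testing.assert_allclose(row, expected, atol=1e-10)

    def test_sinusoid_peak_scale_matches_oracle(self):
        n = 240
        t = np.arange(n)
        scales = np.arange(2.0, 40.0, 2.0)
        for period in (24.0, 48.0):
            x = np.sin(2 * np.pi * t / period)
            sig = EcgSignal(samples=x, fs=360)
            got = wavelet_transform(sig, scales)
            oracle = _ricker_direct(x, scales)
            # implementation agrees with brute force away from the edges
            np.testing.assert_allclose(got[:, 60:180], oracle[:, 60:180], atol=1e-8)
            best = scales[np.argmax(np.abs(got[:, 60:180]).max(axis=1))]
            best_oracle = scales[np.argmax(np.abs(oracle[:, 60:180]).max(axis=1))]
            assert best == best_oracle

    def test_peak_scale_tracks_period(self):
        # doubling the period should (roughly) double the best-matching scale
        n, scales = 720, np.arange(1.0, 60.0, 1.0)
        t = np.arange(n)
        best = []
        for period in (24.0, 48.0):
            x = np.sin(2 * np.pi * t / period)
            out = wavelet_transform(EcgSignal(samples=x, fs=360), scales)
            best.append(scales[np.argmax(np.abs(out[:, 100:-100]).max(axis=1))])
        assert 1.6 <= best[1] / best[0] <= 2.4

    def test_validation(self):
        sig = EcgSignal(samples=np.ones(50), fs=360)
        with pytest.raises(ValueError):
            wavelet_transform(sig, [])
        with pytest.raises(ValueError):
            wavelet_transform(sig, [-1.0])


def _band_power(x, fs, f_hi):
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    power = np.abs(np.fft.rfft(x)) ** 2
    return float(power[(freqs > 0) & (freqs < f_hi)].sum())


class TestDenoise:
    def test_zero_signal(self):
        sig = EcgSignal(samples=np.zeros(1024) + 0.0, fs=360)
        out = denoise(sig)
        assert len(out) == 1024 and out.fs == 360
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_baseline_wander_removed(self):
        drifty, _ = synth_ecg(SynthEcgConfig(n_beats=30, seed=3,
                                             baseline_amp=0.5, baseline_freq=0.3))
        out = denoise(drifty)
        before = _band_power(drifty.samples, drifty.fs, 0.5)
        after = _band_power(out.samples, drifty.fs, 0.5)
        assert after <= 0.1 * before

    def test_clean_signal_preserved(self):
        sig, _ = synth_ecg(SynthEcgConfig(n_beats=30, seed=3))
        out = denoise(sig)
        assert np.corrcoef(out.samples, sig.samples)[0, 1] >= 0.99

    def test_idempotent_within_tolerance(self):
        sig, _ = synth_ecg(SynthEcgConfig(n_beats=20, seed=5, noise_sd=0.05))
        once = denoise(sig)
        twice = denoise(once)
        rms = np.sqrt(np.mean(once.samples**2))
        assert np.sqrt(np.mean((twice.samples - once.samples) ** 2)) < 0.05 * rms

    def test_too_short(self):
        sig = EcgSignal(samples=np.ones(100), fs=360)
        with pytest.raises(ValueError):
            denoise(sig, DenoiseConfig(levels=9))

    def test_config_round_trip(self):
        cfg = DenoiseConfig(levels=8, detail_threshold_levels={1},
                            baseline_detail_levels={8}, threshold_rule="hard")
        assert DenoiseConfig.from_dict(cfg.to_dict()) == cfg

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DenoiseConfig(levels=0)
        with pytest.raises(ValueError):
            DenoiseConfig(levels=3, detail_threshold_levels={5})
        with pytest.raises(ValueError):
            DenoiseConfig(threshold_rule="banana")


def _ann(r):
    return BeatAnnotation(r, "N", "N")


class TestSegmentBeats:
    def test_window_definition(self):
        x = np.arange(1000, dtype=float)
        sig = EcgSignal(samples=x, fs=360)
        beats, dropped = segment_beats(sig, [_ann(200)])
        assert dropped == 0
        assert len(beats) == 1
        np.testing.assert_array_equal(beats[0].samples, x[110:345])
        assert len(beats[0].samples) == BEAT_LEN == 235
        assert beats[0].samples[beats[0].r_offset] == 200.0

    def test_truncated_windows_dropped(self):
        sig = EcgSignal(samples=np.ones(1000), fs=360)
        beats, dropped = segment_beats(sig, [_ann(50), _ann(500), _ann(900)])
        assert len(beats) == 1 and dropped == 2

    def test_excluded_class_dropped(self):
        sig = EcgSignal(samples=np.ones(1000), fs=360)
        anns = [BeatAnnotation(500, "/", "EXCLUDED")]
        beats, dropped = segment_beats(sig, anns)
        assert beats == [] and dropped == 1

    def test_counts_partition(self, rng):
        n = 5000
        sig = EcgSignal(samples=rng.normal(size=n), fs=360)
        anns = [_ann(int(r)) for r in np.sort(rng.choice(n, size=40, replace=False))]
        beats, dropped = segment_beats(sig, anns)
        assert len(beats) + dropped == len(anns)
        for b in beats:
            assert len(b.samples) == BEAT_LEN
            r = b.source[1]
            assert PRE_R <= r < n - POST_R

    def test_annotation_outside_record(self):
        sig = EcgSignal(samples=np.ones(100), fs=360)
        with pytest.raises(ValueError):
            segment_beats(sig, [_ann(100)])
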