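"""Wavelet spectrograms, syncope detection, cluster inference, FFT bands."""

import numpy as np
import pytest

from synckit import spectral
from synckit.session import AnalysisWindow, TimeSeries


def _sine(freq, duration=10.0, fs=500.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return TimeSeries(amp * np.sin(2 * np.pi * freq * t), fs)


class TestNotch:
    def test_60hz_attenuated(self):
        out = spectral.notch_filter(_sine(60.0))
        assert np.std(out.values) < 0.1 * np.std(_sine(60.0).values)

    def test_passband_preserved(self):
        out = spectral.notch_filter(_sine(10.0))
        assert abs(np.std(out.values) / np.std(_sine(10.0).values) - 1) < 0.05

    def test_mixture_recovers_clean_component(self):
        fs = 500.0
        t = np.arange(int(10 * fs)) / fs
        mixed = TimeSeries(np.sin(2 * np.pi * 60 * t) + np.sin(2 * np.pi * 10 * t), fs)
        out = spectral.notch_filter(mixed)
        clean = np.sin(2 * np.pi * 10 * t)
        r = np.corrcoef(out.values, clean)[0, 1]
        assert r >= 0.99

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            spectral.notch_filter(TimeSeries(np.zeros(100), 100.0))


class TestWaveletPower:
    def test_frequency_grid(self):
        f = spectral.morse_freqs()
        assert f.size == 80 and f[0] == 0.5 and f[-1] == 120.0
        assert np.all(np.diff(f) > 0)

    def test_baseline_rows_normalize_to_one(self, rng):
        ts = TimeSeries(rng.standard_normal(5000), 500.0)
        spec = spectral.wavelet_power(ts, AnalysisWindow(0.0, 10.0))
        np.testing.assert_allclose(spec.power.mean(axis=1), 1.0, atol=1e-6)
        assert spec.normalized

    def test_normalization_idempotent(self, rng):
        ts = TimeSeries(rng.standard_normal(5000), 500.0)
        base = AnalysisWindow(0.0, 10.0)
        spec = spectral.wavelet_power(ts, base)
        before = spec.power.copy()
        spectral._normalize_inplace(spec, base)
        np.testing.assert_allclose(spec.power, before, rtol=1e-12)

    @pytest.mark.parametrize("i", range(40, 80, 8))
    def test_sinusoid_peaks_at_nearest_bin(self, i):
        """A pure tone localizes at its own frequency row (sweep over bins
        in the band the syncope statistic uses)."""
        freqs = spectral.morse_freqs()
        ts = _sine(freqs[i])
        spec = spectral.wavelet_power(ts, baseline=None, time_downsample=5)
        sl = (spec.times > 1.0) & (spec.times < 9.0)
        rows = np.argmax(spec.power[:, sl], axis=0)
        assert np.median(rows) == i

    def test_step_fixture_power_ratio(self, fixtures):
        """Amplitude x0.3 implies normalized band power ~0.09 (power ~ amp^2)."""
        spec = spectral.wavelet_power(fixtures["step_lfp"],
                                      AnalysisWindow(0.0, 10.0),
                                      time_downsample=5)
        band = spec.band_mean((8.0, 100.0))
        inside = band[(spec.times > 12) & (spec.times < 18)].mean()
        assert abs(inside - 0.09) < 0.02

    def test_zero_baseline_power_raises(self):
        ts = TimeSeries(np.zeros(5000), 500.0)
        with pytest.raises(FloatingPointError, match="Hz"):
            spectral.wavelet_power(ts, AnalysisWindow(0.0, 10.0))


class TestDetectSyncope:
    def test_constant_power_yields_none(self):
        spec = spectral.WaveletSpectrogram(
            freqs=spectral.morse_freqs(), times=np.arange(0, 30, 0.1),
            power=np.ones((80, 300)), normalized=True)
        assert spectral.detect_syncope(spec, 5.0) is None

    def test_step_fixture_onset_and_offset(self, fixtures):
        spec = spectral.wavelet_power(fixtures["step_lfp"],
                                      AnalysisWindow(0.0, 10.0),
                                      time_downsample=5)
        ev = spectral.detect_syncope(spec, 5.0)
        assert abs(ev.onset - 10.0) <= 1.0
        assert abs(ev.offset - 20.0) <= 1.0
        assert ev.offset > ev.onset

    def test_onset_monotone_in_threshold(self, fixtures):
        spec = spectral.wavelet_power(fixtures["step_lfp"],
                                      AnalysisWindow(0.0, 10.0),
                                      time_downsample=5)
        onsets = [spectral.detect_syncope(spec, 5.0, onset_frac=f).onset
                  for f in (0.6, 0.5, 0.4, 0.3)]
        assert all(b >= a for a, b in zip(onsets, onsets[1:]))

    def test_band_outside_freqs_rejected(self):
        spec = spectral.WaveletSpectrogram(
            freqs=spectral.morse_freqs(), times=np.arange(10.0),
            power=np.ones((80, 10)), normalized=True)
        with pytest.raises(ValueError):
            spectral.detect_syncope(spec, 0.0, band=(500.0, 600.0))


class TestContrastMap:
    def test_identical_conditions_zero_map(self, rng):
        trials = rng.standard_normal((4, 5, 6))
        np.testing.assert_allclose(spectral.light_contrast_map(trials, trials), 0.0)

    def test_constant_offset_recovered(self, rng):
        off = rng.standard_normal((3, 5, 6))
        on = off + 2.5
        np.testing.assert_allclose(spectral.light_contrast_map(on, off), 2.5)

    def test_single_trial_conditions(self, rng):
        on = rng.standard_normal((1, 4, 4))
        off = rng.standard_normal((1, 4, 4))
        np.testing.assert_allclose(spectral.light_contrast_map(on, off),
                                   on[0] - off[0])

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            spectral.light_contrast_map(rng.standard_normal((2, 4, 4)),
                                        rng.standard_normal((2, 4, 5)))


class TestClusterPermutation:
    def test_injected_drop_found_as_negative_cluster(self):
        from synckit.validation import cluster_effect_experiment
        r = cluster_effect_experiment(seed=1, n_perm=300)
        assert r["n_negative_clusters"] >= 1 and r["overlaps_injection"]

    def test_identical_trials_degenerate_null(self, rng):
        trials = np.tile(rng.standard_normal((1, 6, 8)), (4, 1, 1))
        with pytest.warns(UserWarning, match="identical"):
            res = spectral.cluster_permutation_test(trials, trials, n_perm=100,
                                                    rng=0)
        assert len(res.clusters) == 0

    def test_too_few_permutations_rejected(self, rng):
        a = rng.standard_normal((3, 4, 4))
        with pytest.raises(ValueError):
            spectral.cluster_permutation_test(a, a, n_perm=10)


class TestBandPowerFFT:
    def test_pure_alpha_tone(self):
        df = spectral.band_power_fft(_sine(10.0, duration=8.0))
        bands = df.drop(columns="t_start")
        frac = bands["alpha"] / bands.sum(axis=1)
        assert (frac >= 0.95).all()

    def test_two_tone_split(self):
        fs = 500.0
        t = np.arange(int(8 * fs)) / fs
        ts = TimeSeries(np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 50 * t), fs)
        df = spectral.band_power_fft(ts).drop(columns="t_start")
        total = df.sum(axis=1)
        assert np.allclose(df["delta"] / total, 0.5, atol=0.05)
        assert np.allclose(df["low_gamma"] / total, 0.5, atol=0.05)

    def test_white_noise_power_tracks_bandwidth(self, rng):
        ts = TimeSeries(rng.standard_normal(int(120 * 500)), 500.0)
        df = spectral.band_power_fft(ts).drop(columns="t_start").mean()
        widths = {"delta": 3, "theta": 4, "alpha": 5, "beta": 17,
                  "low_gamma": 29, "high_gamma": 59}
        density = np.array([df[k] / w for k, w in widths.items()])
        assert density.max() / density.min() < 1.25

    def test_partial_segment_dropped(self):
        df = spectral.band_power_fft(_sine(10.0, duration=7.3))
        assert len(df) == 3

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            spectral.band_power_fft(_sine(10.0, duration=1.0))
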