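"""Segmenting, windowed periodograms, cross spectra, robust ensembles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hdqeeg.io import EEGRecording, apply_average_reference
from hdqeeg.spectra import (
    F_STEP,
    FREQUENCIES,
    N_BINS,
    SpectrumSet,
    bartlett_weights,
    channel_pairs,
    compute_spectrum_set,
    cross_spectrum,
    robust_ensemble_estimate,
    segment_power_spectrum,
    segment_signal,
)


def _avg_rec(seconds, seed=0, rate=250.0):
    gen = np.random.default_rng(seed)
    rec = EEGRecording(gen.normal(0, 10, (19, int(rate * seconds))), rate)
    return apply_average_reference(rec)


class TestSegmentation:
    @pytest.mark.parametrize("seconds,expected", [(180, 179), (2, 1), (5.5, 4)])
    def test_segment_counts(self, seconds, expected):
        ens = segment_signal(_avg_rec(seconds))
        assert ens.count == expected
        assert ens.segments.shape == (expected, 19, 500)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="2-s"):
            segment_signal(_avg_rec(1.5))

    def test_requires_average_reference(self):
        rec = EEGRecording(np.zeros((19, 1000)), 250.0)
        with pytest.raises(ValueError, match="average-referenced"):
            segment_signal(rec)


class TestBartlett:
    def test_closed_form_small_windows(self):
        np.testing.assert_allclose(bartlett_weights(3), [0, 1, 0])
        np.testing.assert_allclose(bartlett_weights(5), [0, 0.5, 1, 0.5, 0])

    @given(st.integers(min_value=2, max_value=600))
    @settings(max_examples=40, derandomize=True)
    def test_symmetry_and_formula(self, n):
        w = bartlett_weights(n)
        np.testing.assert_allclose(w, w[::-1], atol=1e-12)
        k = np.arange(n)
        np.testing.assert_allclose(w, 1 - np.abs(2 * k / (n - 1) - 1), atol=1e-12)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            bartlett_weights(1)


class TestPeriodogram:
    def test_sinusoid_peak_and_parseval(self):
        fs, n = 250.0, 500
        t = np.arange(n) / fs
        x = 3.0 * np.sin(2 * np.pi * 10.0 * t)
        spec = segment_power_spectrum(x, fs)
        assert spec.shape == (N_BINS,)
        assert FREQUENCIES[np.argmax(spec)] == 10.0
        # Parseval on the full (untruncated) grid
        w = bartlett_weights(n)
        X = np.fft.rfft(w * x)
        full = 2 * np.abs(X) ** 2 / (fs * np.sum(w**2))
        full[0] /= 2
        full[-1] /= 2
        time_power = np.sum((w * x) ** 2) / np.sum(w**2)
        freq_power = np.sum(full) * (fs / n)
        assert abs(time_power - freq_power) / time_power < 1e-6

    def test_zero_segment_gives_zero_spectrum(self):
        assert np.all(segment_power_spectrum(np.zeros(500), 250.0) == 0.0)

    def test_white_noise_is_flat_on_average(self):
        gen = np.random.default_rng(0)
        segs = gen.normal(size=(4000, 500))
        specs = np.stack([segment_power_spectrum(s, 250.0) for s in segs])
        mean = specs.mean(axis=0)[1:]  # skip DC (not doubled)
        expected = 2.0 / 250.0  # one-sided density of unit-variance noise
        se = specs.std(axis=0)[1:] / np.sqrt(len(segs))
        assert np.all(np.abs(mean - expected) < 4 * se + 1e-4)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="45"):
            segment_power_spectrum(np.zeros(180), 90.0)


class TestCrossSpectrum:
    def test_self_pair_equals_power_spectrum_exactly(self):
        gen = np.random.default_rng(1)
        x = gen.normal(size=500)
        assert np.array_equal(cross_spectrum(x, x, 250.0), segment_power_spectrum(x, 250.0))

    def test_identical_channels_perfect_coherence(self):
        gen = np.random.default_rng(2)
        x = gen.normal(size=500)
        np.testing.assert_allclose(
            cross_spectrum(x, x.copy(), 250.0), segment_power_spectrum(x, 250.0)
        )

    def test_independent_channels_below_auto_level(self):
        gen = np.random.default_rng(3)
        n_seg = 3000
        a = gen.normal(size=(n_seg, 500))
        b = gen.normal(size=(n_seg, 500))
        cross = np.stack([cross_spectrum(a[i], b[i], 250.0) for i in range(n_seg)])
        auto = np.stack([segment_power_spectrum(a[i], 250.0) for i in range(n_seg)])
        # |XY*| of independent signals averages below the auto level
        # (Rayleigh mean of a complex-Gaussian product magnitude)
        assert cross[:, 1:].mean() < 0.95 * auto[:, 1:].mean()


class TestRobustEnsemble:
    def test_identical_segments_are_a_fixed_point(self):
        spec = np.abs(np.random.default_rng(0).normal(size=91)) + 1.0
        ens = np.tile(spec, (50, 1))
        np.testing.assert_allclose(robust_ensemble_estimate(ens), spec, rtol=1e-9)

    def test_single_segment_returned_unchanged(self):
        spec = np.arange(91.0)
        np.testing.assert_array_equal(robust_ensemble_estimate(spec[None, :]), spec)

    def test_resists_gross_outlier(self):
        gen = np.random.default_rng(4)
        v = 5.0
        clean = gen.normal(v, 0.05, size=(100, 1))
        contaminated = clean.copy()
        contaminated[0, 0] = 1000 * v
        est = robust_ensemble_estimate(contaminated)[0]
        assert abs(est - v) / v < 0.01
        assert abs(contaminated.mean() - v) / v > 5  # the mean is wrecked

    def test_five_times_closer_than_mean_under_contamination(self):
        gen = np.random.default_rng(5)
        clean = gen.normal(10.0, 1.0, size=(100, 91))
        reference = robust_ensemble_estimate(clean)
        contaminated = clean.copy()
        contaminated[:10] *= 50.0  # 10% gross contamination
        robust_dev = np.abs(robust_ensemble_estimate(contaminated) - reference)
        mean_dev = np.abs(contaminated.mean(axis=0) - reference)
        assert np.all(mean_dev >= 5 * robust_dev)

    def test_consistent_with_mean_for_gaussian_ensemble(self):
        gen = np.random.default_rng(6)
        x = gen.normal(3.0, 1.0, size=(2000, 20))
        est = robust_ensemble_estimate(x)
        se = x.std(axis=0, ddof=1) / np.sqrt(len(x))
        assert np.all(np.abs(est - x.mean(axis=0)) < 3 * se)

    def test_segment_order_irrelevant(self):
        gen = np.random.default_rng(7)
        x = np.abs(gen.normal(2.0, 0.5, size=(60, 91)))
        shuffled = x[gen.permutation(60)]
        np.testing.assert_allclose(
            robust_ensemble_estimate(x), robust_ensemble_estimate(shuffled), rtol=1e-9
        )

    def test_zero_mad_falls_back_to_median(self):
        x = np.ones((10, 3))
        x[0, 0] = 5.0
        est = robust_ensemble_estimate(x)
        np.testing.assert_allclose(est, [1.0, 1.0, 1.0])


class TestSpectrumSet:
    def test_dimensions(self, short_spectrum_set):
        ss = short_spectrum_set
        assert ss.single_channel.shape == (19, 91)
        assert ss.pairwise.shape == (171, 91)
        assert len(channel_pairs()) == 171
        assert ss.all_spectra().size == 17290
        assert len(ss.spectrum_names) == 190
        assert ss.frequencies[1] - ss.frequencies[0] == F_STEP

    def test_nonnegative_and_finite(self, short_spectrum_set):
        values = short_spectrum_set.all_spectra()
        assert np.all(values >= 0) and np.all(np.isfinite(values))

    def test_pair_order_lexicographic(self, short_spectrum_set):
        pairs = short_spectrum_set.pair_index
        assert pairs[0] == (0, 1) and pairs[-1] == (17, 18)
        assert all(i < j for i, j in pairs)

    def test_tabular_round_trip(self, short_spectrum_set):
        from hdqeeg.spectra import frame_to_spectrum_set, spectrum_set_to_frame

        frame = spectrum_set_to_frame(short_spectrum_set)
        assert frame.shape == (91, 191)  # frequency + 190 spectra
        back = frame_to_spectrum_set(frame, short_spectrum_set.channel_labels)
        np.testing.assert_array_equal(back.single_channel, short_spectrum_set.single_channel)
        np.testing.assert_array_equal(back.pairwise, short_spectrum_set.pairwise)
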