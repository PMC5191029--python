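"""Hilbert spectral analysis: IA/IF, spectrum grid, MS, IE, DS, smoothing."""

import numpy as np
import pytest

from hhtar import hsa

FS = 100.0


def make_channel(amp, freq, n):
    """AnalyticChannel with prescribed constant or per-sample amp/freq."""
    a = np.broadcast_to(np.asarray(amp, dtype=float), (n,)).copy()
    f = np.broadcast_to(np.asarray(freq, dtype=float), (n,)).copy()
    return hsa.AnalyticChannel(amplitude=a, phase=np.zeros(n), frequency=f)


class TestAnalyticSignal:
    def test_unit_tone_amplitude(self):
        t = np.arange(1000) / FS
        ch = hsa.analytic_signal(np.cos(2 * np.pi * 5 * t), FS)
        interior = ch.amplitude[100:-100]
        assert interior.min() > 0.98 and interior.max() < 1.02

    def test_zero_series(self):
        ch = hsa.analytic_signal(np.zeros(64), FS)
        np.testing.assert_array_equal(ch.amplitude, 0.0)

    def test_am_envelope_recovery(self):
        t = np.arange(1000) / FS
        env = 1 + 0.5 * np.cos(2 * np.pi * 1 * t)
        ch = hsa.analytic_signal(env * np.cos(2 * np.pi * 10 * t), FS)
        sl = slice(100, 900)
        rms = np.sqrt(np.mean((ch.amplitude[sl] - env[sl]) ** 2))
        assert rms / np.mean(env[sl]) < 0.05

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            hsa.analytic_signal(np.zeros(4), FS)


class TestInstantaneousFrequency:
    def test_constant_tone(self):
        t = np.arange(1000) / FS
        ch = hsa.analytic_signal(np.cos(2 * np.pi * 5 * t), FS)
        interior = ch.frequency[100:-100]
        assert np.all(np.abs(interior - 5.0) < 0.1)

    def test_linear_chirp(self):
        t = np.arange(1000) / FS
        # 1 -> 5 Hz over 10 s: f(t) = 1 + 0.4 t
        phase = 2 * np.pi * (1.0 * t + 0.2 * t**2)
        ch = hsa.analytic_signal(np.cos(phase), FS)
        sl = slice(100, 900)
        f_true = 1.0 + 0.4 * t[sl]
        rms = np.sqrt(np.mean((ch.frequency[sl] - f_true) ** 2))
        assert rms < 0.2

    def test_constant_phase_gives_zero(self):
        f = hsa.instantaneous_frequency(np.full(100, 1.3), FS)
        np.testing.assert_array_equal(f, 0.0)


class TestHilbertSpectrum:
    def test_single_tone_concentration(self):
        t = np.arange(1000) / FS
        ch = hsa.analytic_signal(np.cos(2 * np.pi * 5 * t), FS)
        interior = hsa.AnalyticChannel(
            ch.amplitude[100:-100], ch.phase[100:-100], ch.frequency[100:-100]
        )
        spec = hsa.hilbert_spectrum([interior], FS, n_bins=50)
        # 5 Hz falls exactly on a bin edge; IF jitter of order 1e-10 puts
        # samples on either side, so count the two bins meeting at the edge
        bin_5hz = int(5.0 / spec.df)
        mass = spec.H[:, bin_5hz - 1 : bin_5hz + 1].sum()
        assert mass / spec.H.sum() >= 0.95

    def test_empty_channel_list_gives_zero_grid(self):
        spec = hsa.hilbert_spectrum([], FS, n_bins=16, n_samples=10)
        assert spec.H.shape == (10, 16)
        np.testing.assert_array_equal(spec.H, 0.0)

    def test_grid_energy_matches_ie_in_disjoint_bins(self):
        n = 200
        ch1 = make_channel(1.5, 5.0, n)
        ch2 = make_channel(0.7, 20.0, n)
        spec = hsa.hilbert_spectrum([ch1, ch2], FS, n_bins=50)
        ie = hsa.instantaneous_energy([ch1, ch2])
        grid_energy = (spec.H**2).sum(axis=1)  # unit bin-width convention
        np.testing.assert_allclose(grid_energy, ie, rtol=1e-6)

    def test_out_of_range_frequencies_clip_to_edge_bins(self):
        n = 16
        ch = make_channel(1.0, -3.0, n)
        spec = hsa.hilbert_spectrum([ch], FS, n_bins=10)
        assert spec.H[:, 0].sum() == pytest.approx(n)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            hsa.hilbert_spectrum([], FS, n_bins=1, n_samples=4)


class TestMarginalSpectrum:
    def test_tone_mass_is_amplitude_times_duration(self):
        t = np.arange(1000) / FS  # T = 10 s, A = 1
        ch = hsa.analytic_signal(np.cos(2 * np.pi * 5 * t), FS)
        spec = hsa.hilbert_spectrum([ch], FS, n_bins=50)
        ms = hsa.marginal_spectrum(spec)
        bin_5hz = int(5.0 / spec.df)
        mass = ms[bin_5hz - 1 : bin_5hz + 2].sum()
        assert mass == pytest.approx(10.0, rel=0.05)

    def test_zero_grid_gives_zero(self):
        spec = hsa.hilbert_spectrum([], FS, n_bins=8, n_samples=5)
        np.testing.assert_array_equal(hsa.marginal_spectrum(spec), 0.0)

    def test_binning_refinement(self):
        """Total MS mass is invariant to the bin count and the peak
        location converges to the tone frequency as bins are refined."""
        t = np.arange(1000) / FS
        ch = hsa.analytic_signal(np.cos(2 * np.pi * 5.3 * t), FS)
        interior = hsa.AnalyticChannel(
            ch.amplitude[100:-100], ch.phase[100:-100], ch.frequency[100:-100]
        )
        masses, errors = [], []
        for n_bins in (16, 64, 256):
            spec = hsa.hilbert_spectrum([interior], FS, n_bins=n_bins)
            ms = hsa.marginal_spectrum(spec)
            masses.append(ms.sum())
            errors.append(abs(spec.freq_centers[ms.argmax()] - 5.3))
            assert errors[-1] <= spec.df
        np.testing.assert_allclose(masses, masses[0], rtol=1e-12)
        assert errors[0] >= errors[-1]

    def test_additivity_over_disjoint_tones(self):
        n = 300
        ch1 = make_channel(1.0, 4.0, n)
        ch2 = make_channel(2.0, 18.0, n)
        joint = hsa.marginal_spectrum(hsa.hilbert_spectrum([ch1, ch2], FS, n_bins=64))
        m1 = hsa.marginal_spectrum(hsa.hilbert_spectrum([ch1], FS, n_bins=64))
        m2 = hsa.marginal_spectrum(hsa.hilbert_spectrum([ch2], FS, n_bins=64))
        np.testing.assert_allclose(joint, m1 + m2, atol=1e-9)


class TestInstantaneousEnergy:
    def test_constant_amplitude(self):
        t = np.arange(1000) / FS
        ch = hsa.analytic_signal(2 * np.cos(2 * np.pi * 5 * t), FS)
        interior = hsa.instantaneous_energy([ch])[100:-100]
        np.testing.assert_allclose(interior, 4.0, rtol=0.05)

    def test_no_channels_gives_zero(self):
        np.testing.assert_array_equal(hsa.instantaneous_energy([], n_samples=7), 0.0)


class TestDegreeOfStationarity:
    def test_time_constant_spectrum_is_stationary(self):
        n = 100
        ch = make_channel(1.3, 7.0, n)
        spec = hsa.hilbert_spectrum([ch], FS, n_bins=25)
        ds, defined = hsa.degree_of_stationarity(spec)
        assert np.all(ds[defined] == pytest.approx(0.0, abs=1e-12))
        assert np.all(ds[~defined] == 0.0)

    def test_two_point_alternation_gives_one(self):
        # H alternates 0 and 2A in one bin: n = A, DS = ((1-0)^2 + (1-2)^2)/2 = 1
        n = 100
        amp = np.where(np.arange(n) % 2 == 0, 2.0, 0.0)
        ch = make_channel(amp, 7.0, n)
        spec = hsa.hilbert_spectrum([ch], FS, n_bins=25)
        ds, defined = hsa.degree_of_stationarity(spec)
        bin_7 = int(7.0 / spec.df)
        assert defined[bin_7]
        assert ds[bin_7] == pytest.approx(1.0)

    def test_am_tone_matches_direct_formula(self):
        t = np.arange(512) / FS
        env = 1 + 0.5 * np.sin(2 * np.pi * 0.5 * t)
        ch = hsa.analytic_signal(env * np.cos(2 * np.pi * 10 * t), FS)
        spec = hsa.hilbert_spectrum([ch], FS, n_bins=64)
        ds, defined = hsa.degree_of_stationarity(spec)
        carrier = int(10.0 / spec.df)
        assert defined[carrier] and ds[carrier] > 0
        # brute force the defining time integral on the grid
        H = spec.H
        for f in np.flatnonzero(defined):
            n_f = H[:, f].mean()
            expected = np.mean((1 - H[:, f] / n_f) ** 2)
            assert ds[f] == pytest.approx(expected, abs=1e-9)

    def test_nonnegative_and_finite(self):
        rng = np.random.default_rng(2)
        ch = make_channel(rng.uniform(0, 2, 64), rng.uniform(0, 49, 64), 64)
        spec = hsa.hilbert_spectrum([ch], FS, n_bins=32)
        ds, _ = hsa.degree_of_stationarity(spec)
        assert np.all(np.isfinite(ds)) and np.all(ds >= 0)


class TestSmoothSpectrum:
    def test_zero_grid_stays_zero(self):
        spec = hsa.hilbert_spectrum([], FS, n_bins=16, n_samples=16)
        np.testing.assert_array_equal(hsa.smooth_spectrum(spec).H, 0.0)

    def test_impulse_reproduces_normalized_kernel(self):
        spec = hsa.hilbert_spectrum([], FS, n_bins=32, n_samples=32)
        spec.H[16, 16] = 5.0
        sm = hsa.smooth_spectrum(spec)
        assert sm.H.sum() == pytest.approx(5.0, abs=1e-12)
        kernel = hsa._gaussian_kernel(hsa.SMOOTH_SIZE, hsa.SMOOTH_SIGMA)
        np.testing.assert_allclose(sm.H[12:21, 12:21], 5.0 * kernel, atol=1e-12)

    def test_mass_conserved_for_interior_support(self):
        rng = np.random.default_rng(4)
        spec = hsa.hilbert_spectrum([], FS, n_bins=40, n_samples=40)
        spec.H[10:30, 10:30] = rng.uniform(0, 3, size=(20, 20))
        sm = hsa.smooth_spectrum(spec)
        assert sm.H.sum() == pytest.approx(spec.H.sum(), rel=1e-9)

    def test_small_grid_returned_unchanged_with_warning(self):
        spec = hsa.hilbert_spectrum([], FS, n_bins=4, n_samples=4)
        with pytest.warns(UserWarning):
            out = hsa.smooth_spectrum(spec)
        assert out is spec
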