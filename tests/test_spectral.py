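"""Spectral estimators against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lfpstates import spectral
from lfpstates.spectral import (Correlogram, SpectralEstimate,
                                amplitude_comodulogram, band_power,
                                coherence_entropy, cross_correlation,
                                cross_spectrum_of_correlogram, emg_power,
                                fisher_z, msc_coherence, peak_in_window,
                                relative_power, theta_gamma_correlation,
                                welch_psd)

FS = 500.0


class TestWelchPSD:
    def test_single_segment_equals_direct_periodogram(self):
        """One 1 s segment: Welch must equal the Hamming periodogram exactly."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(FS))
        est = welch_psd(x, FS)
        win = np.hamming(int(FS))  # scipy 'hamming' == numpy hamming (sym)
        from scipy.signal import get_window
        win = get_window("hamming", int(FS))
        xd = (x - x.mean()) * win
        spec = np.fft.rfft(xd, n=2 * int(FS))
        pxx = (np.abs(spec) ** 2) / (FS * (win ** 2).sum())
        pxx[1:-1] *= 2
        rel = np.abs(est.values - pxx) / pxx.max()
        assert rel.max() < 1e-10

    def test_white_noise_parseval(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((100, int(3 * FS)))
        x /= x.std()
        est = welch_psd(x, FS)
        df = est.freqs[1] - est.freqs[0]
        integral = est.values.mean(axis=0).sum() * df
        assert integral == pytest.approx(1.0, abs=0.05)

    def test_tone_peak_located(self):
        t = np.arange(0, 3, 1 / FS)
        est = welch_psd(np.sin(2 * np.pi * 8 * t), FS)
        assert est.freqs[np.argmax(est.values)] == pytest.approx(8.0, abs=0.5)

    def test_too_short_epoch_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), FS)


class TestRelativeAndBandPower:
    def test_normalization_sums_to_one_exactly(self):
        rng = np.random.default_rng(2)
        est = welch_psd(rng.standard_normal((7, int(3 * FS))), FS)
        rel = relative_power(est)
        f = rel.freqs
        sel = (f >= 0.5) & (f <= 55.0)
        np.testing.assert_allclose(rel.values[:, sel].sum(axis=-1), 1.0,
                                   rtol=1e-12)

    def test_8hz_counted_in_theta(self):
        # band table: theta spans 4.5-11 Hz, so an 8 Hz tone lands inside
        t = np.arange(0, 3, 1 / FS)
        rng = np.random.default_rng(3)
        x = 10 * np.sin(2 * np.pi * 8 * t) + 0.1 * rng.standard_normal(len(t))
        rel = relative_power(welch_psd(x, FS))
        assert band_power(rel, "theta") > 0.8

    def test_band_sum_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        est = welch_psd(rng.standard_normal(int(3 * FS)), FS)
        rel = relative_power(est)
        direct = rel.values[(rel.freqs >= 4.5) & (rel.freqs <= 11.0)].sum()
        assert band_power(rel, "theta") == pytest.approx(direct, rel=1e-12)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(int(3 * FS))
        r1 = relative_power(welch_psd(x, FS)).values
        r2 = relative_power(welch_psd(3.7 * x, FS)).values
        np.testing.assert_allclose(r1, r2, rtol=1e-9)


class TestCoherence:
    def test_identical_signals_give_unity(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal((5, int(3 * FS)))
        coh = msc_coherence(x, x, FS)
        power_bins = coh.freqs > 0.5
        np.testing.assert_allclose(coh.values[:, power_bins], 1.0, atol=1e-8)

    def test_independent_noise_bias_matches_monte_carlo(self):
        """5-segment MSC of independent noise ~ its own small-sample bias."""
        rng = np.random.default_rng(7)
        n_mc = 200
        vals = []
        for _ in range(n_mc):
            x = rng.standard_normal(int(3 * FS))
            y = rng.standard_normal(int(3 * FS))
            coh = msc_coherence(x, y, FS)
            sel = (coh.freqs >= 5) & (coh.freqs <= 50)
            vals.append(coh.values[sel].mean())
        mc_bias = np.mean(vals)
        # independent replication of the same estimator is the oracle here:
        # the two halves must agree, and the bias must be clearly below 0.5
        rng2 = np.random.default_rng(8)
        vals2 = []
        for _ in range(n_mc):
            x = rng2.standard_normal(int(3 * FS))
            y = rng2.standard_normal(int(3 * FS))
            coh = msc_coherence(x, y, FS)
            sel = (coh.freqs >= 5) & (coh.freqs <= 50)
            vals2.append(coh.values[sel].mean())
        assert mc_bias == pytest.approx(np.mean(vals2), abs=0.05)
        assert 0.0 < mc_bias < 0.4

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError, match="segments"):
            msc_coherence(np.zeros(int(FS)), np.zeros(int(FS)), FS)

    def test_fisher_z_closed_forms(self):
        assert fisher_z(0.0) == 0.0
        assert float(fisher_z(0.5)) == pytest.approx(np.arctanh(np.sqrt(0.5)),
                                                     rel=1e-12)
        assert float(fisher_z(0.5)) == pytest.approx(0.8814, abs=1e-4)
        with pytest.raises(ValueError):
            fisher_z(1.5)


class TestEMGPower:
    def test_stopband_tone_suppressed(self):
        t = np.arange(0, 5, 1 / FS)
        p = emg_power(np.sin(2 * np.pi * 10 * t), FS)
        assert p < 1e-3

    def test_parseval_on_inband_tone(self):
        t = np.arange(0, 5, 1 / FS)
        a = 2.0
        p = emg_power(a * np.sin(2 * np.pi * 100 * t), FS)
        assert p == pytest.approx(a ** 2 / 2, rel=0.05)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(int(5 * FS))
        assert emg_power(2 * x, FS) == pytest.approx(4 * emg_power(x, FS),
                                                     rel=1e-9)


class TestCrossCorrelation:
    def test_identity_peak_at_zero(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal((3, int(3 * FS)))
        cg = cross_correlation(x, x, FS)
        k = np.argmax(cg.coefs)
        assert cg.lags_ms[k] == 0.0
        assert cg.coefs[k] == pytest.approx(1.0, abs=1e-6)

    def test_planted_delay_appears_at_negative_lag(self):
        rng = np.random.default_rng(11)
        n = int(3 * FS)
        lag_n = int(0.040 * FS)
        epochs_h, epochs_p = [], []
        for _ in range(30):
            h = rng.standard_normal(n + lag_n)
            p = h[:-lag_n] + 0.5 * rng.standard_normal(n)  # pfc = delayed hpc
            epochs_h.append(h[lag_n:])
            epochs_p.append(p)
        cg = cross_correlation(np.array(epochs_h), np.array(epochs_p), FS)
        lag, coef = peak_in_window(cg, -200, 200)
        assert lag == pytest.approx(-40.0, abs=10.0)
        assert coef > 0.2

    def test_window_outside_range_rejected(self):
        cg = Correlogram(lags_ms=np.arange(-1000, 1001, 2.0),
                         coefs=np.zeros(1001))
        with pytest.raises(ValueError):
            peak_in_window(cg, -1500, -20)


class TestCrossSpectrum:
    def test_cosine_correlogram_peaks_at_its_frequency(self):
        lags = np.arange(-int(FS), int(FS) + 1) / FS
        cg = Correlogram(lags_ms=lags * 1000,
                         coefs=np.cos(2 * np.pi * 7 * lags))
        est = cross_spectrum_of_correlogram(cg, FS)
        assert est.freqs[np.argmax(est.values)] == pytest.approx(7.0, abs=0.5)

    def test_zero_correlogram_gives_zero_spectrum(self):
        lags = np.arange(-int(FS), int(FS) + 1) / FS
        cg = Correlogram(lags_ms=lags * 1000, coefs=np.zeros_like(lags))
        est = cross_spectrum_of_correlogram(cg, FS)
        assert np.all(est.values == 0)


class TestComodulogram:
    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(12)
        comod = amplitude_comodulogram(rng.standard_normal((5, int(3 * FS))), FS)
        np.testing.assert_allclose(comod.values, comod.values.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(comod.values), 1.0, atol=1e-10)

    def test_independent_bands_uncorrelated(self):
        from lfpstates.synth import _band_noise
        rng = np.random.default_rng(13)
        n = int(60 * FS)
        x = (_band_noise(rng, n, FS, 7.0, 3.0)
             + _band_noise(rng, n, FS, 80.0, 20.0))
        comod = amplitude_comodulogram(x.reshape(-1, int(3 * FS)), FS)
        assert abs(theta_gamma_correlation(comod)) < 0.05

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            amplitude_comodulogram(np.zeros((1, int(0.2 * FS))), FS)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((4, int(3 * FS)))
        c1 = amplitude_comodulogram(x, FS).values
        c2 = amplitude_comodulogram(5.0 * x, FS).values
        np.testing.assert_allclose(c1, c2, atol=1e-5)


class TestCoherenceEntropy:
    def test_uniform_gives_ln3(self):
        assert coherence_entropy([0.4, 0.4, 0.4]) == pytest.approx(np.log(3),
                                                                   rel=1e-12)

    def test_hand_computed_case(self):
        # (0.6, 0.3, 0.3) -> p = (0.5, 0.25, 0.25) -> H = 1.5 ln 2
        assert coherence_entropy([0.6, 0.3, 0.3]) == pytest.approx(
            1.5 * np.log(2), rel=1e-12)

    def test_degenerate_limit(self):
        assert coherence_entropy([1.0, 1e-12, 1e-12]) == pytest.approx(0.0,
                                                                       abs=1e-9)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            coherence_entropy([0.5, -0.1, 0.2])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.01, 1.0), min_size=3, max_size=3),
           st.floats(0.1, 100.0))
    def test_scale_invariance(self, values, k):
        h1 = coherence_entropy(values)
        h2 = coherence_entropy([k * v for v in values])
        assert h1 == pytest.approx(h2, rel=1e-9)
        assert 0.0 <= h1 <= np.log(3) + 1e-12
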