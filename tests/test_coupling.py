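"""Tests of coherence, IAAFT surrogates, spectral Granger causality and
power-envelope correlation."""

import numpy as np
import pytest

import pupresp as pr
from pupresp.coupling import csd_matrix, wilson_factorize
from pupresp.spectral import SpectralConfig
from pupresp.timeseries import TimeSeries

FS = 25.0
LIN_CFG = SpectralConfig(halfbandwidth_hz=0.1, f_lo=0.0, f_hi=6.0,
                         n_freqs=121, spacing="linear")


def _spec(x, fs=FS, cfg=None):
    cs, _ = pr.multitaper_spectrum(TimeSeries(np.asarray(x, float), fs), cfg)
    return cs


def _ar2_pair(seed, n=3600, coupling=0.5):
    """Bivariate AR(2) oscillators with x -> y coupling only."""
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    y = np.zeros(n)
    ex = rng.normal(size=n)
    ey = rng.normal(size=n)
    for t in range(2, n):
        x[t] = 0.55 * x[t - 1] - 0.8 * x[t - 2] + ex[t]
        y[t] = 0.55 * y[t - 1] - 0.8 * y[t - 2] + coupling * x[t - 1] + ey[t]
    return x, y


class TestCoherence:
    def test_identical_signals_msc_one(self, rng):
        sx = _spec(rng.normal(size=int(300 * FS)))
        coh = pr.coherence(sx, sx)
        np.testing.assert_allclose(coh.msc, 1.0, atol=1e-12)

    def test_symmetry(self, rng):
        sx = _spec(rng.normal(size=int(300 * FS)))
        sy = _spec(rng.normal(size=int(300 * FS)))
        np.testing.assert_array_equal(pr.coherence(sx, sy).msc,
                                      pr.coherence(sy, sx).msc)

    def test_independent_noise_bias_floor(self, rng):
        """Mean msc of independent white noise sits at the analytic 1/K
        bias of single-segment multitaper coherence."""
        mscs = []
        for _ in range(4):
            sx = _spec(rng.normal(size=int(300 * FS)))
            sy = _spec(rng.normal(size=int(300 * FS)))
            coh = pr.coherence(sx, sy)
            sel = (coh.freqs >= 1) & (coh.freqs <= 6)
            mscs.append(coh.msc[sel].mean())
        k = coh.n_tapers
        assert 0.5 / k <= np.mean(mscs) <= 2.0 / k

    def test_delayed_copy_phase_slope(self, rng):
        """y = x delayed by 1 s: msc near 1 and cross-spectral phase slope
        of 2*pi radians per Hz."""
        x = rng.normal(size=int(300 * FS))
        y = np.roll(x, int(1.0 * FS))
        sx, sy = _spec(x, cfg=LIN_CFG), _spec(y, cfg=LIN_CFG)
        coh = pr.coherence(sx, sy)
        sel = (coh.freqs >= 0.5) & (coh.freqs <= 3)
        # tapering decorrelates shifted copies slightly; msc stays high
        assert coh.msc[sel].min() > 0.7
        assert coh.msc[sel].mean() > 0.85
        cross = np.sum(sx.coeffs * np.conj(sy.coeffs), axis=0)
        phase = np.unwrap(np.angle(cross[sel]))
        # y lags x by 1 s, so X conj(Y) rotates by +2*pi per Hz
        slope = np.polyfit(coh.freqs[sel], phase, 1)[0]
        assert slope == pytest.approx(2 * np.pi, rel=0.02)

    def test_grid_mismatch_raises(self, rng):
        sx = _spec(rng.normal(size=int(300 * FS)))
        sy = _spec(rng.normal(size=int(300 * FS)), cfg=LIN_CFG)
        with pytest.raises(ValueError):
            pr.coherence(sx, sy)


class TestIAAFT:
    def test_sorted_amplitudes_exact(self, clean_subject):
        surr = pr.iaaft_surrogate(clean_subject.pupil, seed=3)
        np.testing.assert_array_equal(np.sort(surr.data),
                                      np.sort(clean_subject.pupil.data))

    def test_amplitude_spectrum_preserved(self, clean_subject):
        from scipy.fft import rfft
        x = clean_subject.pupil.data
        surr = pr.iaaft_surrogate(clean_subject.pupil, seed=3)
        a0 = np.abs(rfft(x))
        a1 = np.abs(rfft(surr.data))
        assert np.linalg.norm(a1 - a0) / np.linalg.norm(a0) < 0.01

    def test_phase_scrambling_destroys_alignment(self, rng):
        """On a broadband record the surrogate decorrelates from the
        original (a single dominant spectral line would instead leave a
        random phase-offset correlation)."""
        resp = pr.generate_respiration(pr.RespirationGenConfig(), 300, FS, 9)
        pupil, _ = pr.generate_pupil(
            pr.PupilGenConfig(a_hippus=0.3, blink_rate_hz=0.0), resp, seed=9)
        for seed in (1, 2):
            surr = pr.iaaft_surrogate(pupil, seed=seed)
            r = np.corrcoef(pupil.data, surr.data)[0, 1]
            assert abs(r) < 0.2

    def test_surrogate_coherence_below_observed(self, rest_cohort_small):
        """Surrogate coherence at the respiratory peak falls below the
        observed coupled coherence for every subject of a coupled cohort."""
        n_below = 0
        for i, s in enumerate(rest_cohort_small):
            clean = pr.preprocess_recording(s.respiration, s.pupil)
            sr, rp = pr.multitaper_spectrum(clean.respiration)
            sp, _ = pr.multitaper_spectrum(clean.pupil)
            surr = pr.iaaft_surrogate(clean.pupil, seed=i)
            ss, _ = pr.multitaper_spectrum(surr)
            band = (sr.freqs >= 0.1) & (sr.freqs <= 1)
            peak = np.argmax(rp.power_db[band])
            orig = pr.coherence(sr, sp).msc[band][peak]
            chance = pr.coherence(sr, ss).msc[band][peak]
            n_below += chance < orig
        assert n_below >= 0.95 * len(rest_cohort_small)


class TestGranger:
    def test_factorization_residual_contract(self):
        """H Sigma H* reconstructs the cross-spectral density to better than
        1e-4 relative error at every bin."""
        x, y = _ar2_pair(seed=0)
        S = csd_matrix(_spec(x, 12.0, LIN_CFG), _spec(y, 12.0, LIN_CFG))
        H, Sigma, resid, _ = wilson_factorize(S)
        recon = H @ Sigma @ np.conj(np.swapaxes(H, 1, 2))
        per_bin = (np.linalg.norm(recon - S, axis=(1, 2))
                   / np.linalg.norm(S, axis=(1, 2)))
        assert per_bin.max() < 1e-4

    def test_direction_recovery_vs_var_oracle(self):
        """Unidirectional AR(2) coupling: the driven direction dominates and
        agrees with a parametric VAR-Granger oracle on the same data."""
        import statsmodels.tsa.api as tsa

        x, y = _ar2_pair(seed=1)
        g = pr.granger_nonparametric(_spec(x, 12.0, LIN_CFG),
                                     _spec(y, 12.0, LIN_CFG))
        band = (g.freqs >= 0.5) & (g.freqs <= 5)
        ours_xy = g.g_x_to_y[band].mean()
        ours_yx = g.g_y_to_x[band].mean()
        assert ours_xy >= 3 * ours_yx

        # oracle: fit a VAR(2) and evaluate spectral Granger from the fitted
        # coefficients analytically
        model = tsa.VAR(np.column_stack([x, y])).fit(2, trend="n")
        sigma = model.sigma_u
        freqs = g.freqs
        omega = 2 * np.pi * freqs / 12.0
        g_or = np.empty(freqs.size)
        for i, w in enumerate(omega):
            a = np.eye(2, dtype=complex)
            for k, Ak in enumerate(model.coefs, start=1):
                a -= Ak * np.exp(-1j * w * k)
            h = np.linalg.inv(a)
            s = h @ sigma @ h.conj().T
            syy = np.real(s[1, 1])
            cond = sigma[0, 0] - sigma[0, 1] ** 2 / sigma[1, 1]
            g_or[i] = np.log(syy / (syy - cond * np.abs(h[1, 0]) ** 2))
        oracle_xy = g_or[band].mean()
        assert ours_xy == pytest.approx(oracle_xy, rel=0.3)

    def test_independent_pair_below_null_quantile(self):
        """Independent AR pairs stay below the simulation-calibrated null
        95th percentile of the coupled statistic."""
        null_means = []
        for seed in range(12):
            x, _ = _ar2_pair(seed=100 + seed, coupling=0.0)
            _, y = _ar2_pair(seed=200 + seed, coupling=0.0)
            g = pr.granger_nonparametric(_spec(x, 12.0, LIN_CFG),
                                         _spec(y, 12.0, LIN_CFG))
            null_means.append(max(g.g_x_to_y.mean(), g.g_y_to_x.mean()))
        q95 = np.quantile(null_means, 0.95)
        x, y = _ar2_pair(seed=3)
        g = pr.granger_nonparametric(_spec(x, 12.0, LIN_CFG),
                                     _spec(y, 12.0, LIN_CFG))
        assert g.g_x_to_y.mean() > q95
        assert g.g_y_to_x.mean() <= q95 * 1.5

    def test_total_interdependence_identity(self):
        """G_xy + G_yx + instantaneous term equals -ln(1 - C) within 10%
        for near-Gaussian AR data (an algebraic identity at exact
        factorization)."""
        x, y = _ar2_pair(seed=5)
        sx, sy = _spec(x, 12.0, LIN_CFG), _spec(y, 12.0, LIN_CFG)
        g = pr.granger_nonparametric(sx, sy)
        S = csd_matrix(sx, sy)
        sxx = np.real(S[:, 0, 0])
        syy = np.real(S[:, 1, 1])
        msc = np.abs(S[:, 0, 1]) ** 2 / (sxx * syy)
        sig = g.noise_cov
        det_s = sxx * syy - np.abs(S[:, 0, 1]) ** 2
        cx = sig[0, 0] - sig[0, 1] ** 2 / sig[1, 1]
        cy = sig[1, 1] - sig[0, 1] ** 2 / sig[0, 0]
        g_inst = np.log((syy - cx * np.abs(g.transfer[:, 1, 0]) ** 2)
                        * (sxx - cy * np.abs(g.transfer[:, 0, 1]) ** 2)
                        / det_s)
        total = g.g_x_to_y + g.g_y_to_x + g_inst
        expected = -np.log(1 - msc)
        sel = expected > 0.1  # compare where interdependence is substantial
        assert np.allclose(total[sel], expected[sel], rtol=0.1)

    def test_nonuniform_grid_rejected(self, rng):
        sx = _spec(rng.normal(size=int(300 * FS)))
        with pytest.raises(ValueError, match="linear"):
            pr.granger_nonparametric(sx, sx)


class TestEnvelopeCorrelation:
    def _env(self, x, fs=FS):
        return pr.tfr_multitaper(TimeSeries(x, fs))

    def test_self_correlation_diagonal_one(self, rng):
        t = np.arange(int(300 * FS)) / FS
        x = np.sin(2 * np.pi * 0.25 * t) * (1 + 0.5 * np.sin(2 * np.pi * 0.01 * t))
        x += 0.1 * rng.normal(size=t.size)
        e = self._env(x)
        c = pr.envelope_correlation(e, e)
        np.testing.assert_allclose(np.diag(c.r), 1.0, atol=1e-12)
        assert np.all(np.abs(c.r) <= 1.0 + 1e-12)

    def test_fisher_transform(self, rng):
        t = np.arange(int(300 * FS)) / FS
        x = np.sin(2 * np.pi * 0.25 * t) + 0.3 * rng.normal(size=t.size)
        y = 0.3 * rng.normal(size=t.size) + np.sin(2 * np.pi * 0.5 * t)
        c = pr.envelope_correlation(self._env(x), self._env(y))
        finite = np.isfinite(c.z)
        np.testing.assert_allclose(c.z[finite], np.arctanh(c.r[finite]))

    def test_anticorrelated_amplitude_modulation(self, rng):
        """Opposite slow AM of two carriers shows up as negative r at the
        carrier-frequency cell."""
        t = np.arange(int(300 * FS)) / FS
        m = np.sin(2 * np.pi * t / 150.0)
        x = (1 + 0.8 * m) * np.sin(2 * np.pi * 0.25 * t)
        y = (1 - 0.8 * m) * np.sin(2 * np.pi * 0.6 * t)
        x += 0.05 * rng.normal(size=t.size)
        y += 0.05 * rng.normal(size=t.size)
        c = pr.envelope_correlation(self._env(x), self._env(y))
        i = np.argmin(np.abs(c.resp_freqs - 0.25))
        j = np.argmin(np.abs(c.pupil_freqs - 0.6))
        assert c.r[i, j] < -0.5

    def test_short_record_insufficient_windows(self, rng):
        x = rng.normal(size=int(80 * FS))
        e = self._env(x)
        with pytest.raises(ValueError, match="insufficient"):
            pr.envelope_correlation(e, e)


class TestBlur:
    def test_zero_sigma_identity(self, rng):
        m = rng.normal(size=(8, 8))
        np.testing.assert_allclose(pr.blur_matrix(m, sigma=0.0), m)

    def test_constant_matrix_unchanged(self):
        m = np.full((6, 6), 2.5)
        np.testing.assert_allclose(pr.blur_matrix(m), m, atol=1e-12)

    def test_impulse_mass_preserved(self):
        m = np.zeros((15, 15))
        m[7, 7] = 1.0
        out = pr.blur_matrix(m)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
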