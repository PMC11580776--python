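"""Pairwise coupling measures for a respiration / pupil signal pair.

Magnitude-squared coherence from multitaper complex spectra; IAAFT surrogate
time series (amplitude-distribution and power-spectrum preserving, phase
scrambling) as the chance-level reference; nonparametric spectral Granger
causality via Wilson's spectral matrix factorization; and frequency-by-
frequency Pearson correlation of power envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import gaussian_filter

from .spectral import ComplexSpectrum, PowerEnvelope
from .timeseries import TimeSeries

__all__ = [
    "CoherenceSpectrum",
    "GrangerConfig",
    "GrangerSpectra",
    "FreqFreqCorrelation",
    "coherence",
    "iaaft_surrogate",
    "wilson_factorize",
    "granger_nonparametric",
    "envelope_correlation",
    "blur_matrix",
]

_MSC_FLOOR = 1e-30


@dataclass
class CoherenceSpectrum:
    freqs: np.ndarray
    msc: np.ndarray
    log_msc: np.ndarray  # decadic log of msc, the statistics scale
    n_tapers: int


@dataclass
class GrangerConfig:
    f_lo: float = 0.0
    f_hi: float = 6.0
    f_step: float = 0.05
    halfbandwidth_hz: float = 0.1
    factorization_tol: float = 1e-9
    factorization_max_iter: int = 500

    def grid(self) -> np.ndarray:
        n = int(round((self.f_hi - self.f_lo) / self.f_step)) + 1
        return self.f_lo + self.f_step * np.arange(n)


@dataclass
class GrangerSpectra:
    freqs: np.ndarray
    g_x_to_y: np.ndarray
    g_y_to_x: np.ndarray
    transfer: np.ndarray      # (n_freqs, 2, 2) factorized transfer function
    noise_cov: np.ndarray     # 2x2 innovation covariance
    resid_rel: float          # relative Frobenius residual of S - H Sigma H*
    n_iter: int


@dataclass
class FreqFreqCorrelation:
    resp_freqs: np.ndarray
    pupil_freqs: np.ndarray
    r: np.ndarray
    z: np.ndarray  # Fisher transform, atanh(r)


def coherence(sx: ComplexSpectrum, sy: ComplexSpectrum) -> CoherenceSpectrum:
    """Magnitude-squared coherence across tapers of a single record.

    msc(f) = |sum_k X_k conj(Y_k)|^2 / (sum_k |X_k|^2 * sum_k |Y_k|^2).
    Under independence its expectation sits at the single-segment bias floor
    of roughly 1/K.
    """
    if sx.coeffs.shape != sy.coeffs.shape or not np.allclose(sx.freqs, sy.freqs):
        raise ValueError("spectra must share grid and taper count")
    # cross-spectrum in explicit real arithmetic: multiplication commutes and
    # IEEE subtraction negates exactly, so msc(x, y) == msc(y, x) bit-exact
    # (complex multiply may contract to FMA and lose that)
    xr, xi = sx.coeffs.real, sx.coeffs.imag
    yr, yi = sy.coeffs.real, sy.coeffs.imag
    cross_re = np.sum(xr * yr + xi * yi, axis=0)
    cross_im = np.sum(xi * yr - xr * yi, axis=0)
    sxx = np.sum(xr ** 2 + xi ** 2, axis=0)
    syy = np.sum(yr ** 2 + yi ** 2, axis=0)
    denom = np.clip(sxx * syy, _MSC_FLOOR, None)
    msc = np.clip((cross_re ** 2 + cross_im ** 2) / denom, 0.0, 1.0)
    log_msc = np.log10(np.clip(msc, _MSC_FLOOR, None))
    return CoherenceSpectrum(sx.freqs.copy(), msc, log_msc, sx.n_tapers)


def iaaft_surrogate(ts: TimeSeries, n_iter_max: int = 100, tol: float = 1e-8,
                    seed: int = 0) -> TimeSeries:
    """Iterative amplitude-adjusted Fourier transform surrogate.

    Starting from a random shuffle, alternately impose the original Fourier
    amplitude spectrum and rank-remap onto the original sorted values, until
    the relative change of the spectral mismatch drops below ``tol`` or
    ``n_iter_max`` is reached.  The last step is the value remap, so the
    sorted output equals the sorted input exactly while the power spectrum is
    preserved approximately and the phases are scrambled.
    """
    x = ts.data
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    rng = np.random.default_rng(seed)
    sorted_x = np.sort(x)
    target_amp = np.abs(sp_fft.rfft(x))
    target_norm = np.linalg.norm(target_amp)
    s = rng.permutation(x)
    prev_mismatch = np.inf
    for _ in range(n_iter_max):
        spec = sp_fft.rfft(s)
        phases = np.angle(spec)
        s = sp_fft.irfft(target_amp * np.exp(1j * phases), n=x.size)
        ranks = np.argsort(np.argsort(s))
        s = sorted_x[ranks]
        mismatch = np.linalg.norm(np.abs(sp_fft.rfft(s)) - target_amp)
        mismatch /= target_norm
        if prev_mismatch - mismatch < tol * max(prev_mismatch, 1e-12):
            break
        prev_mismatch = mismatch
    out = ts.copy()
    out.data = s
    out.extras = {"iaaft_mismatch": float(mismatch)}
    return out


# ---------------------------------------------------------------------------
# Wilson spectral matrix factorization and nonparametric Granger causality
# ---------------------------------------------------------------------------

def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal part of a Hermitian-valued spectral function on the full
    two-sided grid: keep non-negative lags, split the lag-0 coefficient as
    B0 = triu(g0) - diag(g0)/2 so that B0 + B0^T = g0."""
    m = g.shape[0]
    gam = np.real(sp_fft.ifft(g, axis=0))
    causal = np.zeros_like(gam)
    half = m // 2
    causal[1:half] = gam[1:half]
    g0 = gam[0]
    causal[0] = np.triu(g0) - 0.5 * np.diag(np.diag(g0))
    # the lag m/2 coefficient is shared between the causal part and its
    # conjugate; keeping half of it makes the split exact on the grid
    causal[half] = 0.5 * gam[half]
    return sp_fft.fft(causal, axis=0)


def wilson_factorize(S: np.ndarray, tol: float = 1e-9, max_iter: int = 500
                     ) -> tuple:
    """Factorize a cross-spectral density S(f) = H(f) Sigma H(f)* by Wilson's
    iterative algorithm.

    ``S`` has shape (n_freqs, n, n) on a uniform grid from 0 to the Nyquist
    frequency inclusive.  Returns ``(H, Sigma, resid_rel, n_iter)`` where
    ``resid_rel`` is the relative Frobenius residual of the reconstruction.
    """
    S = np.asarray(S, dtype=complex)
    nf, nc, _ = S.shape
    m = 2 * (nf - 1)
    Sfull = np.empty((m, nc, nc), dtype=complex)
    Sfull[:nf] = S
    # conjugate half: S(-f) = conj(S(f)) elementwise (Hermitian matrices)
    Sfull[nf:] = np.conj(S[m - np.arange(nf, m)])
    gamma0 = np.real(np.mean(Sfull, axis=0))
    # symmetrize and regularize the lag-0 covariance before Cholesky
    gamma0 = 0.5 * (gamma0 + gamma0.T)
    gamma0 += np.eye(nc) * (1e-12 * np.trace(gamma0) / nc + 1e-300)
    psi = np.tile(np.linalg.cholesky(gamma0).T, (m, 1, 1)).astype(complex)
    eye = np.eye(nc)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Sfull @ np.conj(np.swapaxes(psi_inv, 1, 2)) + eye
        gp = _plus_operator(g)
        psi_new = psi @ gp
        num = np.linalg.norm(psi_new - psi)
        den = np.linalg.norm(psi)
        psi = psi_new
        if not np.isfinite(num):
            raise RuntimeError(
                f"Wilson factorization diverged at iteration {n_iter}")
        if num < tol * den:
            break
    A0 = np.real(np.mean(psi, axis=0))  # lag-0 coefficient of psi
    Sigma = A0 @ A0.T
    H = psi[:nf] @ np.linalg.inv(A0)
    recon = psi[:nf] @ np.conj(np.swapaxes(psi[:nf], 1, 2))
    resid = np.linalg.norm(recon - S) / max(np.linalg.norm(S), 1e-300)
    return H, Sigma, float(resid), n_iter


def csd_matrix(sx: ComplexSpectrum, sy: ComplexSpectrum) -> np.ndarray:
    """2x2 cross-spectral density per frequency from taper cross-products."""
    X, Y = sx.coeffs, sy.coeffs
    S = np.empty((X.shape[1], 2, 2), dtype=complex)
    S[:, 0, 0] = np.mean(np.abs(X) ** 2, axis=0)
    S[:, 1, 1] = np.mean(np.abs(Y) ** 2, axis=0)
    S[:, 0, 1] = np.mean(X * np.conj(Y), axis=0)
    S[:, 1, 0] = np.conj(S[:, 0, 1])
    return S


def granger_nonparametric(sx: ComplexSpectrum, sy: ComplexSpectrum,
                          cfg: GrangerConfig = None) -> GrangerSpectra:
    """Nonparametric spectral Granger causality for a signal pair.

    Builds the 2x2 cross-spectral density from taper cross-products on the
    linear frequency grid, factorizes it into transfer function H and
    innovation covariance Sigma with Wilson's algorithm, and forms

        G_{x->y}(f) = ln[ S_yy / (S_yy - (Sig_xx - Sig_xy^2/Sig_yy)|H_yx|^2) ]

    and symmetrically for the reverse direction.
    """
    cfg = cfg or GrangerConfig()
    freqs = sx.freqs
    steps = np.diff(freqs)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("Granger requires a uniform (linear) frequency grid")
    S = csd_matrix(sx, sy)
    # light diagonal loading for numerical safety at near-line spectra
    load = 1e-10 * np.real(np.trace(S.mean(axis=0))) / 2.0
    S = S + load * np.eye(2)
    H, Sigma, resid, n_iter = wilson_factorize(
        S, cfg.factorization_tol, cfg.factorization_max_iter)
    Sxx = np.real(S[:, 0, 0])
    Syy = np.real(S[:, 1, 1])
    sig_x_cond = Sigma[0, 0] - Sigma[0, 1] ** 2 / Sigma[1, 1]
    sig_y_cond = Sigma[1, 1] - Sigma[0, 1] ** 2 / Sigma[0, 0]
    denom_y = Syy - sig_x_cond * np.abs(H[:, 1, 0]) ** 2
    denom_x = Sxx - sig_y_cond * np.abs(H[:, 0, 1]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        g_xy = np.log(Syy / np.clip(denom_y, 1e-300, None))
        g_yx = np.log(Sxx / np.clip(denom_x, 1e-300, None))
    g_xy = np.clip(np.nan_to_num(g_xy), 0.0, None)
    g_yx = np.clip(np.nan_to_num(g_yx), 0.0, None)
    return GrangerSpectra(freqs.copy(), g_xy, g_yx, H, Sigma, resid, n_iter)


# ---------------------------------------------------------------------------
# Power-envelope correlation
# ---------------------------------------------------------------------------

def envelope_correlation(ex: PowerEnvelope, ey: PowerEnvelope,
                         min_windows: int = 8) -> FreqFreqCorrelation:
    """Pearson correlation over time of every envelope row of ``ex`` with
    every row of ``ey`` (dB scale), plus the Fisher z transform.

    Rows must share the time axis; each cell uses the jointly finite window
    centers of its two rows and requires at least ``min_windows`` of them.
    """
    if ex.times.shape != ey.times.shape or not np.allclose(ex.times, ey.times):
        raise ValueError("envelopes must share the time axis")
    nx, ny = ex.freqs.size, ey.freqs.size
    r = np.full((nx, ny), np.nan)
    for i in range(nx):
        xi = ex.power_db[i]
        fin_x = np.isfinite(xi)
        for j in range(ny):
            yj = ey.power_db[j]
            m = fin_x & np.isfinite(yj)
            if m.sum() < min_windows:
                raise ValueError(
                    "insufficient temporal samples: fewer than "
                    f"{min_windows} shared windows for rows ({i},{j})")
            a = xi[m] - xi[m].mean()
            b = yj[m] - yj[m].mean()
            denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
            r[i, j] = (a * b).sum() / denom if denom > 0 else 0.0
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1.0, 1.0))
    return FreqFreqCorrelation(ex.freqs.copy(), ey.freqs.copy(), r, z)


def blur_matrix(m: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    """2-D Gaussian smoothing with reflective boundaries (default 0.5 px)."""
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix must be finite")
    if sigma <= 0:
        return m.copy()
    return gaussian_filter(m, sigma=sigma, mode="reflect")
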