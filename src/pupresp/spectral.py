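"""Multitaper spectral estimation.

Full-record power and complex spectra use DPSS (Slepian) tapers with a
half-bandwidth of 0.05 Hz by default; records are zero-padded to 600 s before
the transform so all recordings share one spectral grid (1/600 Hz step)
regardless of their length, and the requested analysis grid (log-spaced
0.065-6 Hz by default) is realized by nearest-bin lookup on that padded grid.
The taper count follows K = floor(2*T*W) - 1 with T the actual record length.
Power is reported in decibels (10*log10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.signal.windows import dpss

from .timeseries import TimeSeries

__all__ = [
    "SpectralConfig",
    "TFRConfig",
    "ComplexSpectrum",
    "PowerSpectrum",
    "PowerEnvelope",
    "taper_count",
    "multitaper_spectrum",
    "gradient_spectrum",
    "tfr_multitaper",
]

DB_FLOOR = 1e-30  # power clipped here before the log so spectra stay finite


@dataclass
class SpectralConfig:
    halfbandwidth_hz: float = 0.05
    pad_to_s: float = 600.0
    f_lo: float = 0.065
    f_hi: float = 6.0
    n_freqs: int = 128
    spacing: str = "log"  # "log" | "linear"

    def grid(self) -> np.ndarray:
        if self.spacing == "log":
            if self.f_lo <= 0:
                raise ValueError("f_lo must be positive for log spacing")
            return np.geomspace(self.f_lo, self.f_hi, self.n_freqs)
        return np.linspace(self.f_lo, self.f_hi, self.n_freqs)


@dataclass
class TFRConfig:
    n_freqs: int = 36
    f_lo: float = 0.065
    f_hi: float = 2.0
    cycles_per_window: float = 9.0
    overlap_frac: float = 0.5
    halfbandwidth_hz: float = 0.2

    def grid(self) -> np.ndarray:
        return np.geomspace(self.f_lo, self.f_hi, self.n_freqs)


@dataclass
class ComplexSpectrum:
    """Per-taper complex Fourier coefficients on a realized frequency grid.

    ``coeffs`` has shape (n_tapers, n_freqs) and is scaled so the taper-mean
    of |coeff|^2 is the two-sided power per padded-FFT bin.
    """

    freqs: np.ndarray
    coeffs: np.ndarray
    n_tapers: int
    record_len_s: float
    fs: float

    def power(self) -> np.ndarray:
        """One-sided taper-mean power at each grid frequency."""
        p = np.mean(np.abs(self.coeffs) ** 2, axis=0)
        one_sided = np.where(self.freqs > 0, 2.0, 1.0)
        return p * one_sided


@dataclass
class PowerSpectrum:
    freqs: np.ndarray
    power_db: np.ndarray


@dataclass
class PowerEnvelope:
    """Frequency-by-time decibel power from sliding multitaper windows.

    Rows share one time axis (window centers); cells whose window does not
    fit inside the record are NaN.
    """

    freqs: np.ndarray
    times: np.ndarray
    power_db: np.ndarray


def taper_count(record_len_s: float, halfbandwidth_hz: float) -> int:
    """K = floor(2*T*W) - 1 (T = record length in s, W = half-bandwidth)."""
    return int(np.floor(2.0 * record_len_s * halfbandwidth_hz)) - 1


def _tapers(n: int, fs: float, halfbandwidth_hz: float,
            allow_single: bool = False) -> np.ndarray:
    T = n / fs
    k = taper_count(T, halfbandwidth_hz)
    if k < 1:
        if not allow_single:
            raise ValueError(
                "record too short for requested smoothing "
                f"(T={T:.1f}s, W={halfbandwidth_hz}Hz gives K={k})")
        k = 1
    nw = T * halfbandwidth_hz
    return _dpss_cached(n, round(max(nw, 0.6), 9), k)


from functools import lru_cache


@lru_cache(maxsize=64)
def _dpss_cached(n: int, nw: float, k: int) -> np.ndarray:
    wins = np.atleast_2d(dpss(n, nw, Kmax=k))
    wins = wins / np.sqrt(np.sum(wins ** 2, axis=1, keepdims=True))
    wins.setflags(write=False)
    return wins


def _nearest_bins(requested: np.ndarray, n_pad: int, fs: float) -> np.ndarray:
    step = fs / n_pad
    idx = np.round(np.asarray(requested) / step).astype(int)
    return np.clip(idx, 0, n_pad // 2)


def multitaper_spectrum(ts: TimeSeries, cfg: SpectralConfig = None
                        ) -> tuple:
    """Multitaper complex and power spectra of a full record.

    Returns ``(ComplexSpectrum, PowerSpectrum)``.  The record is zero-padded
    to ``cfg.pad_to_s`` (grid step 1/pad_to_s Hz) and the requested grid is
    mapped to the nearest padded bins; duplicate bins at the low end of a log
    grid are allowed.
    """
    cfg = cfg or SpectralConfig()
    n = ts.n_samples
    T = n / ts.fs
    if T > cfg.pad_to_s + 1e-9:
        raise ValueError("record longer than pad_to_s")
    n_pad = int(round(cfg.pad_to_s * ts.fs))
    tapers = _tapers(n, ts.fs, cfg.halfbandwidth_hz)
    x = ts.data - ts.data.mean()
    coeffs_full = sp_fft.rfft(tapers * x[None, :], n=n_pad, axis=1)
    coeffs_full /= np.sqrt(n_pad)
    bins = _nearest_bins(cfg.grid(), n_pad, ts.fs)
    freqs = bins * ts.fs / n_pad
    cspec = ComplexSpectrum(freqs, coeffs_full[:, bins], tapers.shape[0],
                            T, ts.fs)
    power_db = 10.0 * np.log10(np.clip(cspec.power(), DB_FLOOR, None))
    return cspec, PowerSpectrum(freqs, power_db)


def full_grid_power(ts: TimeSeries, cfg: SpectralConfig = None) -> tuple:
    """Taper-mean power on the complete padded FFT grid (conjugate half
    folded in), so summing over bins recovers the taper-weighted variance
    (Parseval).  Returns ``(freqs, power)``."""
    cfg = cfg or SpectralConfig()
    n = ts.n_samples
    n_pad = int(round(cfg.pad_to_s * ts.fs))
    tapers = _tapers(n, ts.fs, cfg.halfbandwidth_hz)
    x = ts.data - ts.data.mean()
    coeffs = sp_fft.rfft(tapers * x[None, :], n=n_pad, axis=1)
    p = np.mean(np.abs(coeffs) ** 2, axis=0) / n_pad
    freqs = sp_fft.rfftfreq(n_pad, d=1.0 / ts.fs)
    fold = np.full(p.shape, 2.0)
    fold[0] = 1.0
    if n_pad % 2 == 0:
        fold[-1] = 1.0
    return freqs, p * fold


def gradient_spectrum(ts: TimeSeries, cfg: SpectralConfig = None) -> PowerSpectrum:
    """Power spectrum of the first-difference (gradient) series.

    Differentiation multiplies power by ~(2*pi*f)^2, which flattens a 1/f^2
    background and leaves narrowband peak locations untouched -- the peak
    extraction input for power spectra.
    """
    x = np.diff(ts.data) * ts.fs
    if np.allclose(x, 0):
        raise ValueError("degenerate signal: gradient is identically zero")
    _, pspec = multitaper_spectrum(TimeSeries(x, ts.fs), cfg)
    return pspec


def tfr_multitaper(ts: TimeSeries, cfg: TFRConfig = None) -> PowerEnvelope:
    """Sliding-window multitaper power envelopes.

    Each frequency uses a window of ``cycles_per_window`` cycles; all
    frequencies share one time axis with centers spaced by half the shortest
    window, so consecutive windows of every row overlap by at least
    ``overlap_frac``.  Cells whose window exceeds the record are NaN.
    """
    cfg = cfg or TFRConfig()
    freqs = cfg.grid()
    fs = ts.fs
    n = ts.n_samples
    shortest = cfg.cycles_per_window / cfg.f_hi
    dt = shortest * (1.0 - cfg.overlap_frac)
    times = np.arange(shortest / 2.0, ts.duration_s - shortest / 2.0 + 1e-9, dt)
    if times.size == 0:
        raise ValueError("record shorter than one analysis window")
    power = np.full((freqs.size, times.size), np.nan)
    x = ts.data - ts.data.mean()
    for i, f in enumerate(freqs):
        win_n = int(round(cfg.cycles_per_window / f * fs))
        if win_n > n:
            continue
        tapers = _tapers(win_n, fs, cfg.halfbandwidth_hz, allow_single=True)
        t_idx = np.arange(win_n)
        probes = tapers * np.exp(-2j * np.pi * f * t_idx / fs)[None, :]
        centers = np.round(times * fs).astype(int)
        starts = centers - win_n // 2
        valid = (starts >= 0) & (starts + win_n <= n)
        if not valid.any():
            continue
        segs = np.lib.stride_tricks.sliding_window_view(x, win_n)
        c = segs[starts[valid]] @ probes.T  # (n_windows, K)
        p = np.mean(np.abs(c) ** 2, axis=1) * 2.0 / win_n
        power[i, valid] = 10.0 * np.log10(np.clip(p, DB_FLOOR, None))
    return PowerEnvelope(freqs, times, power)
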