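"""Seeded synthetic cohorts of paired respiration / pupil recordings.

The generator emulates the statistical structure the analysis pipeline
assumes: nonsinusoidal breathing around 0.25 Hz with harmonics and a slow
Ornstein-Uhlenbeck drift of the instantaneous rate; pupil traces carrying a
quasi-rhythmic hippus near 0.19 Hz, a 1/f background, blink dips, and a
lagged respiration-driven component of controllable strength.  Condition
presets cover rest, task, normal/deep breathing and an uncoupled null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = [
    "RespirationGenConfig",
    "PupilGenConfig",
    "Subject",
    "CohortDataset",
    "PRESETS",
    "generate_respiration",
    "generate_pupil",
    "generate_cohort",
    "write_cohort",
    "load_cohort",
]


@dataclass
class RespirationGenConfig:
    """Parameters of the synthetic respiration-belt trace.

    ``f0`` is the fundamental breathing rate in Hz; ``harmonic_amps`` are the
    relative amplitudes of harmonics 1..H of the phase waveform (breathing is
    periodic but nonsinusoidal, so real belt spectra show harmonic peaks).
    The instantaneous rate drifts as an Ornstein-Uhlenbeck process with
    stationary SD ``rate_jitter_sd`` (Hz) and correlation time
    ``jitter_timescale_s``.  ``noise_sd`` adds broadband sensor noise as a
    fraction of ``amplitude`` so the belt spectrum has a finite noise floor.
    """

    f0: float = 0.25
    harmonic_amps: tuple = (1.0, 0.35, 0.12)
    rate_jitter_sd: float = 0.02
    jitter_timescale_s: float = 30.0
    amplitude: float = 1.0
    noise_sd: float = 0.02

    def __post_init__(self):
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if any(a < 0 for a in self.harmonic_amps) or not len(self.harmonic_amps):
            raise ValueError("harmonic_amps must be non-negative and non-empty")
        if self.rate_jitter_sd >= self.f0:
            raise ValueError("rate_jitter_sd must stay below f0")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass
class PupilGenConfig:
    """Parameters of the synthetic pupil-size trace.

    The trace is the sum of an intrinsic hippus oscillation (amplitude
    ``a_hippus`` at ``f_hippus``, with its own slow OU phase drift), a
    respiration-driven component ``a_coupled * sin(phi_resp(t - lag_s))``
    re-using the respiration generator's phase, 1/f background noise with
    slope ``pink_exponent``, and blink artifacts: piecewise-linear dips of
    ``blink_depth_sd`` robust SDs at Poisson event times.
    """

    f_hippus: float = 0.19
    a_hippus: float = 1.0
    a_coupled: float = 0.5
    lag_s: float = 0.5
    a_pink: float = 0.7
    pink_exponent: float = 1.5
    blink_rate_hz: float = 0.25
    blink_depth_sd: float = 8.0
    blink_fall_ms: float = 50.0
    blink_recover_ms: float = 150.0
    hippus_jitter_sd: float = 0.0
    hippus_jitter_timescale_s: float = 30.0
    baseline: float = 0.0

    def __post_init__(self):
        for name in ("a_hippus", "a_coupled", "a_pink", "blink_rate_hz",
                     "blink_depth_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.f_hippus <= 0:
            raise ValueError("f_hippus must be positive")


@dataclass
class Subject:
    subject_id: str
    respiration: TimeSeries
    pupil: TimeSeries
    blink_times: np.ndarray
    seed: int
    resp_cfg: RespirationGenConfig
    pupil_cfg: PupilGenConfig


@dataclass
class CohortDataset:
    """Paired recordings for a cohort, plus the generating ground truth."""

    subjects: list
    condition: str
    fs: float
    duration_s: float
    seed: int

    def __len__(self):
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)


def _n_samples(duration_s: float, fs: float) -> int:
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    n = duration_s * fs
    n_int = int(round(n))
    if abs(n - n_int) > 1e-6 or n_int < 1:
        raise ValueError("duration_s * fs must be a positive integer sample count")
    return n_int


def _ou_process(n: int, dt: float, sd: float, tau: float,
                rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck sample path (exact discretization)."""
    if sd == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    x0 = rng.normal(0.0, sd)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - a * a), size=n - 1)
    # AR(1) recursion x_k = a x_{k-1} + innov_k via an IIR filter
    drive = np.concatenate(([x0], innov))
    return lfilter([1.0], [1.0, -a], drive)


def _drifting_phase(f0: float, jitter_sd: float, tau: float, n: int, fs: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Integrated phase of an oscillation with OU-drifting instantaneous rate."""
    f_inst = f0 + _ou_process(n, 1.0 / fs, jitter_sd, tau, rng)
    np.clip(f_inst, 0.05 * f0, None, out=f_inst)
    phi0 = rng.uniform(0.0, 2.0 * np.pi)
    return phi0 + 2.0 * np.pi * np.cumsum(f_inst) / fs


def _pink_noise(n: int, fs: float, exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-SD Gaussian noise with power spectrum ~ 1/f**exponent."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros(freqs.shape)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    coeffs = shape * (rng.normal(size=freqs.shape)
                      + 1j * rng.normal(size=freqs.shape))
    x = np.fft.irfft(coeffs, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_respiration(cfg: RespirationGenConfig, duration_s: float, fs: float,
                         seed: int) -> TimeSeries:
    """Generate a respiration-belt trace.

    The waveform is ``sum_h harmonic_amps[h] * sin(h * phi(t))`` with phase
    integrated from an OU-drifting instantaneous rate, scaled to SD
    ``cfg.amplitude``, plus a small white sensor-noise floor.  Identical seed
    gives identical output.  The instantaneous phase is stored in
    ``extras['phase']`` so the pupil generator can reuse it.
    """
    n = _n_samples(duration_s, fs)
    rng = np.random.default_rng(seed)
    phi = _drifting_phase(cfg.f0, cfg.rate_jitter_sd, cfg.jitter_timescale_s,
                          n, fs, rng)
    x = np.zeros(n)
    for h, amp in enumerate(cfg.harmonic_amps, start=1):
        x += amp * np.sin(h * phi)
    sd = x.std()
    if sd > 0:
        x *= cfg.amplitude / sd
    if cfg.noise_sd > 0:
        x = x + rng.normal(0.0, cfg.noise_sd * cfg.amplitude, size=n)
    return TimeSeries(x, fs, unit="resp_au",
                      extras={"phase": phi, "f0": cfg.f0})


def _blink_profile(depth: float, fall_ms: float, recover_ms: float,
                   fs: float) -> np.ndarray:
    n_fall = max(1, int(round(fall_ms * 1e-3 * fs)))
    n_rec = max(1, int(round(recover_ms * 1e-3 * fs)))
    fall = np.linspace(0.0, -depth, n_fall + 1)[1:]
    rec = np.linspace(-depth, 0.0, n_rec + 1)[1:]
    return np.concatenate([fall, rec])


def generate_pupil(cfg: PupilGenConfig, respiration: TimeSeries,
                   seed: int) -> tuple:
    """Generate a pupil-size trace on the respiration time grid.

    Returns ``(TimeSeries, blink_onset_times_s)``; the blink list is ground
    truth for testing the preprocessing stages.
    """
    n = respiration.n_samples
    fs = respiration.fs
    if cfg.lag_s >= respiration.duration_s:
        raise ValueError("lag_s must be shorter than the recording")
    rng = np.random.default_rng(seed)
    phi_h = _drifting_phase(cfg.f_hippus, cfg.hippus_jitter_sd,
                            cfg.hippus_jitter_timescale_s, n, fs, rng)
    x = cfg.a_hippus * np.sin(phi_h)

    if cfg.a_coupled > 0:
        phi_r = respiration.extras.get("phase")
        if phi_r is None:  # fall back to the analytic-signal phase
            from scipy.signal import hilbert
            phi_r = np.unwrap(np.angle(hilbert(respiration.data)))
        shift = int(round(cfg.lag_s * fs))
        phi_lag = np.empty(n)
        if shift > 0:
            phi_lag[shift:] = phi_r[: n - shift]
            dphi = phi_r[1] - phi_r[0]
            phi_lag[:shift] = phi_r[0] - dphi * np.arange(shift, 0, -1)
        else:
            phi_lag[:] = phi_r
        x = x + cfg.a_coupled * np.sin(phi_lag)

    if cfg.a_pink > 0:
        x = x + cfg.a_pink * _pink_noise(n, fs, cfg.pink_exponent, rng)

    # Blink artifacts: Poisson onsets, linear fall / recovery in units of the
    # robust SD of the composite (pre-blink) trace.
    blink_times = np.array([])
    if cfg.blink_rate_hz > 0:
        n_events = rng.poisson(cfg.blink_rate_hz * respiration.duration_s)
        onsets = np.sort(rng.uniform(0.0, respiration.duration_s, size=n_events))
        mad = np.median(np.abs(x - np.median(x)))
        robust_sd = 1.4826 * mad if mad > 0 else x.std()
        prof = _blink_profile(cfg.blink_depth_sd * robust_sd,
                              cfg.blink_fall_ms, cfg.blink_recover_ms, fs)
        for t0 in onsets:
            i0 = int(round(t0 * fs))
            seg = prof[: max(0, n - i0)]
            x[i0:i0 + seg.size] += seg
        blink_times = onsets

    x = x + cfg.baseline
    ts = TimeSeries(x, fs, unit="pupil_au", extras={"hippus_phase": phi_h})
    return ts, blink_times


# ---------------------------------------------------------------------------
# Cohort presets.  rest_default anchors the breathing fundamental at 0.25 Hz
# and the hippus at 0.19 Hz; normal/deep breathing at 0.27 / 0.21 Hz; the
# task preset has a weak hippus and weak coupling and runs 446 s.
# ---------------------------------------------------------------------------

_REST_RESP = RespirationGenConfig()
_REST_PUPIL = PupilGenConfig()

PRESETS = {
    "rest_default": {
        "resp": _REST_RESP,
        "pupil": _REST_PUPIL,
        "duration_s": 300.0,
        "fs": 600.0,
    },
    "normal_breathing_ds2": {
        "resp": replace(_REST_RESP, f0=0.27),
        "pupil": _REST_PUPIL,
        "duration_s": 300.0,
        "fs": 600.0,
    },
    "deep_breathing": {
        "resp": replace(_REST_RESP, f0=0.21),
        "pupil": replace(_REST_PUPIL, a_hippus=0.5),
        "duration_s": 300.0,
        "fs": 600.0,
    },
    "task_state": {
        "resp": _REST_RESP,
        "pupil": replace(_REST_PUPIL, a_hippus=0.2, a_coupled=0.2),
        "duration_s": 446.0,
        "fs": 600.0,
    },
    "null_uncoupled": {
        "resp": _REST_RESP,
        "pupil": replace(_REST_PUPIL, a_coupled=0.0),
        "duration_s": 300.0,
        "fs": 600.0,
    },
}

# Between-subject scatter (multiplicative, SD as fraction of the preset value)
FREQ_SCATTER_SD = 0.10
AMP_SCATTER_SD = 0.20


def subject_seed(cohort_seed: int, index: int) -> int:
    """Per-subject seed derived deterministically from the cohort seed."""
    return int(cohort_seed) * 10 ** 6 + index


def _scatter(rng, value, sd):
    return value * max(0.1, 1.0 + rng.normal(0.0, sd))


def generate_cohort(preset_name: str, n_subjects: int, seed: int,
                    fs: float = None, duration_s: float = None) -> CohortDataset:
    """Generate a seeded cohort of paired recordings from a named preset.

    Between-subject scatter (10% SD on frequencies, 20% on amplitudes) is
    drawn from each subject's own seed, so two presets generated with the same
    cohort seed share subject-level scatter draws -- the paired-samples
    structure of a within-subject condition contrast.
    """
    if preset_name not in PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(PRESETS)}")
    preset = PRESETS[preset_name]
    fs = preset["fs"] if fs is None else float(fs)
    duration_s = preset["duration_s"] if duration_s is None else float(duration_s)
    subjects = []
    for i in range(int(n_subjects)):
        s_seed = subject_seed(seed, i)
        rng = np.random.default_rng(s_seed)
        # Scatter draws in a fixed order so they pair across presets.
        f_jit = rng.normal(0.0, FREQ_SCATTER_SD)
        fh_jit = rng.normal(0.0, FREQ_SCATTER_SD)
        a_jit = rng.normal(0.0, AMP_SCATTER_SD)
        ah_jit = rng.normal(0.0, AMP_SCATTER_SD)
        ac_jit = rng.normal(0.0, AMP_SCATTER_SD)
        r0, p0 = preset["resp"], preset["pupil"]
        r_cfg = replace(r0,
                        f0=r0.f0 * max(0.1, 1.0 + f_jit),
                        amplitude=r0.amplitude * max(0.1, 1.0 + a_jit))
        p_cfg = replace(p0,
                        f_hippus=p0.f_hippus * max(0.1, 1.0 + fh_jit),
                        a_hippus=p0.a_hippus * max(0.1, 1.0 + ah_jit),
                        a_coupled=p0.a_coupled * max(0.1, 1.0 + ac_jit))
        resp = generate_respiration(r_cfg, duration_s, fs,
                                    seed=rng.integers(2 ** 31))
        pupil, blinks = generate_pupil(p_cfg, resp, seed=rng.integers(2 ** 31))
        subjects.append(Subject(f"sub-{i:03d}", resp, pupil, blinks,
                                s_seed, r_cfg, p_cfg))
    return CohortDataset(subjects, preset_name, fs, duration_s, int(seed))


# ---------------------------------------------------------------------------
# On-disk format: one TSV per subject (time / respiration / pupil) plus a
# JSON sidecar; a manifest lists the files.
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortDataset, directory) -> dict:
    """Write a cohort to ``directory``; returns the manifest (also saved)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for sub in cohort:
        tsv = directory / f"{sub.subject_id}.tsv"
        sidecar = directory / f"{sub.subject_id}.json"
        t = sub.respiration.times
        try:
            with open(tsv, "w") as fh:
                fh.write("time\trespiration\tpupil\n")
                for ti, ri, pi in zip(t, sub.respiration.data, sub.pupil.data):
                    fh.write(f"{ti:.6f}\t{ri:.17g}\t{pi:.17g}\n")
            meta = {
                "fs_hz": cohort.fs,
                "condition": cohort.condition,
                "subject_id": sub.subject_id,
                "seed": sub.seed,
                "duration_s": cohort.duration_s,
                "pupil_measure": "size",
                "blink_times_s": [float(b) for b in sub.blink_times],
            }
            sidecar.write_text(json.dumps(meta, indent=1))
        except OSError as exc:
            raise OSError(f"failed writing {tsv}: {exc}") from exc
        entries.append({"subject_id": sub.subject_id,
                        "tsv": tsv.name, "sidecar": sidecar.name})
    manifest = {"condition": cohort.condition, "fs_hz": cohort.fs,
                "duration_s": cohort.duration_s, "seed": cohort.seed,
                "n_subjects": len(cohort), "files": entries}
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_cohort(directory) -> CohortDataset:
    """Read a cohort written by :func:`write_cohort` (bit-exact round trip)."""
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    subjects = []
    for entry in manifest["files"]:
        meta = json.loads((directory / entry["sidecar"]).read_text())
        df = pd.read_csv(directory / entry["tsv"], sep="\t",
                         float_precision="round_trip",
                         dtype={"respiration": float, "pupil": float})
        fs = float(meta["fs_hz"])
        resp = TimeSeries(df["respiration"].to_numpy(), fs, unit="resp_au")
        pupil = TimeSeries(df["pupil"].to_numpy(), fs, unit="pupil_au")
        subjects.append(Subject(meta["subject_id"], resp, pupil,
                                np.asarray(meta.get("blink_times_s", [])),
                                int(meta["seed"]), None, None))
    return CohortDataset(subjects, manifest["condition"],
                         float(manifest["fs_hz"]),
                         float(manifest["duration_s"]),
                         int(manifest["seed"]))
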