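"""Orchestration of the five analyses over cohort datasets.

Each ``run_*`` function executes one named analysis end-to-end on in-memory
cohorts (see :mod:`pupresp.synthetic` / :func:`pupresp.synthetic.load_cohort`
for the on-disk format) and returns a results bundle: a plain dict holding
group spectra, coupling measures, cluster statistics, peak tables and a
config echo.  ``write_bundle`` serializes a bundle to JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import coupling
from .cluster_stats import ClusterConfig, cluster_perm_paired, \
    cluster_perm_regression, relaxed_cluster_2d, wilcoxon_signed_rank
from .coupling import GrangerConfig, coherence, envelope_correlation, \
    granger_nonparametric, iaaft_surrogate
from .peaks import PeakConfig, find_spectral_peak, jackknife_peaks
from .preprocess import PreprocessConfig, preprocess_recording
from .spectral import SpectralConfig, TFRConfig, gradient_spectrum, \
    multitaper_spectrum, tfr_multitaper
from .synthetic import CohortDataset
from .timeseries import TimeSeries

__all__ = [
    "PROFILES",
    "run_rest_coupling",
    "run_time_windows",
    "run_breathing_modes",
    "run_rest_vs_task",
    "run_blocks_control",
    "run_raw_pupil_control",
    "coherence_vs_surrogate",
    "write_bundle",
]

# permutation counts: the quick profile for iteration, the full profile for
# final inference
PROFILES = {"quick": 1000, "full": 5000}


def _cluster_cfg(profile: str, **kw) -> ClusterConfig:
    return ClusterConfig(n_permutations=PROFILES[profile], **kw)


def _surrogate_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2 ** 31, size=n)


def coherence_vs_surrogate(cohort: CohortDataset, seed: int = 0,
                           profile: str = "quick",
                           pre_cfg: PreprocessConfig = None,
                           spec_cfg: SpectralConfig = None,
                           cluster_cfg: ClusterConfig = None) -> dict:
    """Respiration-pupil coherence against one IAAFT surrogate per subject,
    with the paired cluster permutation test on log10 coherence spectra."""
    pre_cfg = pre_cfg or PreprocessConfig()
    spec_cfg = spec_cfg or SpectralConfig()
    cluster_cfg = cluster_cfg or _cluster_cfg(profile)
    seeds = _surrogate_seeds(seed, len(cohort))
    freqs = None
    log_orig, log_surr, msc_orig, msc_surr = [], [], [], []
    for s_seed, subject in zip(seeds, cohort):
        clean = preprocess_recording(subject.respiration, subject.pupil, pre_cfg)
        r_spec, _ = multitaper_spectrum(clean.respiration, spec_cfg)
        p_spec, _ = multitaper_spectrum(clean.pupil, spec_cfg)
        surr = iaaft_surrogate(clean.pupil, seed=int(s_seed))
        s_spec, _ = multitaper_spectrum(surr, spec_cfg)
        coh = coherence(r_spec, p_spec)
        coh_s = coherence(r_spec, s_spec)
        freqs = coh.freqs
        log_orig.append(coh.log_msc)
        log_surr.append(coh_s.log_msc)
        msc_orig.append(coh.msc)
        msc_surr.append(coh_s.msc)
    log_orig = np.array(log_orig)
    log_surr = np.array(log_surr)
    result = cluster_perm_paired(log_orig, log_surr, cluster_cfg, seed=seed)
    return {
        "freqs": freqs,
        "msc": np.array(msc_orig),
        "msc_surrogate": np.array(msc_surr),
        "log_msc": log_orig,
        "log_msc_surrogate": log_surr,
        "cluster_result": result,
    }


def _granger_block(cohort, seed, pre_cfg, gr_cfg: GrangerConfig,
                   cluster_cfg) -> dict:
    """Directional Granger spectra (resp->pupil and back) plus the surrogate
    control (resp->surrogate-pupil), with both paired cluster contrasts."""
    lin_cfg = SpectralConfig(halfbandwidth_hz=gr_cfg.halfbandwidth_hz,
                             f_lo=gr_cfg.f_lo, f_hi=gr_cfg.f_hi,
                             n_freqs=gr_cfg.grid().size, spacing="linear")
    seeds = _surrogate_seeds(seed + 1, len(cohort))
    g_rp, g_pr, g_rs = [], [], []
    freqs = None
    for s_seed, subject in zip(seeds, cohort):
        clean = preprocess_recording(subject.respiration, subject.pupil, pre_cfg)
        r_spec, _ = multitaper_spectrum(clean.respiration, lin_cfg)
        p_spec, _ = multitaper_spectrum(clean.pupil, lin_cfg)
        surr = iaaft_surrogate(clean.pupil, seed=int(s_seed))
        s_spec, _ = multitaper_spectrum(surr, lin_cfg)
        g = granger_nonparametric(r_spec, p_spec, gr_cfg)
        gs = granger_nonparametric(r_spec, s_spec, gr_cfg)
        freqs = g.freqs
        g_rp.append(g.g_x_to_y)
        g_pr.append(g.g_y_to_x)
        g_rs.append(gs.g_x_to_y)
    g_rp, g_pr, g_rs = map(np.array, (g_rp, g_pr, g_rs))
    return {
        "freqs": freqs,
        "resp_to_pupil": g_rp,
        "pupil_to_resp": g_pr,
        "resp_to_surrogate": g_rs,
        "direction_contrast": cluster_perm_paired(g_rp, g_pr, cluster_cfg,
                                                  seed=seed + 2),
        "surrogate_contrast": cluster_perm_paired(g_rp, g_rs, cluster_cfg,
                                                  seed=seed + 3),
    }


def _envelope_block(cohort, seed, pre_cfg, tfr_cfg: TFRConfig,
                    cluster_cfg) -> dict:
    """Frequency-frequency power-envelope correlations against surrogate,
    blurred, with the relaxed 2-D cluster criterion on the paired t map."""
    seeds = _surrogate_seeds(seed + 4, len(cohort))
    z_orig, z_surr, r_orig = [], [], []
    rf = pf = None
    for s_seed, subject in zip(seeds, cohort):
        clean = preprocess_recording(subject.respiration, subject.pupil, pre_cfg)
        e_r = tfr_multitaper(clean.respiration, tfr_cfg)
        e_p = tfr_multitaper(clean.pupil, tfr_cfg)
        surr = iaaft_surrogate(clean.pupil, seed=int(s_seed))
        e_s = tfr_multitaper(surr, tfr_cfg)
        c = envelope_correlation(e_r, e_p)
        cs = envelope_correlation(e_r, e_s)
        rf, pf = c.resp_freqs, c.pupil_freqs
        z_orig.append(coupling.blur_matrix(c.z))
        z_surr.append(coupling.blur_matrix(cs.z))
        r_orig.append(c.r)
    z_orig = np.array(z_orig)
    z_surr = np.array(z_surr)
    d = z_orig - z_surr
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmap = d.mean(axis=0) / (sd / np.sqrt(n))
    tmap = np.nan_to_num(tmap)
    clusters = relaxed_cluster_2d(tmap, n - 1, cluster_cfg)
    return {
        "resp_freqs": rf,
        "pupil_freqs": pf,
        "r": np.array(r_orig),
        "t_map": tmap,
        "clusters_relaxed": clusters,
    }


def run_rest_coupling(cohort: CohortDataset, seed: int = 0,
                      profile: str = "quick",
                      include_granger: bool = True,
                      include_envelope: bool = True,
                      pre_cfg: PreprocessConfig = None,
                      out_dir=None) -> dict:
    """Resting-state coupling analysis: coherence vs IAAFT surrogate with
    cluster statistics, directional Granger causality with its surrogate
    control, and the power-envelope correlation with relaxed 2-D clusters."""
    pre_cfg = pre_cfg or PreprocessConfig()
    cluster_cfg = _cluster_cfg(profile)
    bundle = _new_bundle("rest_coupling", seed, profile,
                         pre_cfg=pre_cfg, cluster_cfg=cluster_cfg)
    bundle["coherence"] = coherence_vs_surrogate(
        cohort, seed, profile, pre_cfg, cluster_cfg=cluster_cfg)
    if include_granger:
        bundle["granger"] = _granger_block(cohort, seed, pre_cfg,
                                           GrangerConfig(), cluster_cfg)
    if include_envelope:
        bundle["envelope"] = _envelope_block(cohort, seed, pre_cfg,
                                             TFRConfig(), cluster_cfg)
    return _maybe_write(bundle, out_dir)


def run_time_windows(cohort: CohortDataset, seed: int = 0,
                     profile: str = "quick",
                     pre_cfg: PreprocessConfig = None,
                     out_dir=None) -> dict:
    """Trend analysis over three 50%-overlapping half-record windows
    (150 s each for 300 s records): cluster-permutation regression of pupil
    power, respiration power and coherence on the window index."""
    pre_cfg = pre_cfg or PreprocessConfig()
    cluster_cfg = _cluster_cfg(profile)
    win = cohort.duration_s / 2.0
    starts = [0.0, win / 2.0, win]
    resp_p, pupil_p, coh_l = [], [], []
    freqs = None
    for subject in cohort:
        if subject.respiration.duration_s < cohort.duration_s - 1e-9:
            raise ValueError(f"record too short for windows: {subject.subject_id}")
        clean = preprocess_recording(subject.respiration, subject.pupil, pre_cfg)
        rw, pw, cw = [], [], []
        for t0 in starts:
            i0 = int(round(t0 * cohort.fs))
            i1 = i0 + int(round(win * cohort.fs))
            r = TimeSeries(clean.respiration.data[i0:i1], cohort.fs)
            p = TimeSeries(clean.pupil.data[i0:i1], cohort.fs)
            r_spec, r_pow = multitaper_spectrum(r)
            p_spec, p_pow = multitaper_spectrum(p)
            coh = coherence(r_spec, p_spec)
            freqs = coh.freqs
            rw.append(r_pow.power_db)
            pw.append(p_pow.power_db)
            cw.append(coh.log_msc)
        resp_p.append(rw)
        pupil_p.append(pw)
        coh_l.append(cw)
    bundle = _new_bundle("time_windows", seed, profile, pre_cfg=pre_cfg,
                         cluster_cfg=cluster_cfg)
    bundle.update({
        "freqs": freqs,
        "n_windows": len(starts),
        "window_s": win,
        "respiration_trend": cluster_perm_regression(
            np.array(resp_p), cluster_cfg, seed=seed),
        "pupil_trend": cluster_perm_regression(
            np.array(pupil_p), cluster_cfg, seed=seed + 1),
        "coherence_trend": cluster_perm_regression(
            np.array(coh_l), cluster_cfg, seed=seed + 2),
    })
    return _maybe_write(bundle, out_dir)


def _peak_freqs(estimates) -> np.ndarray:
    return np.array([np.nan if e is None else e.freq_hz for e in estimates])


def run_breathing_modes(cohort_deep: CohortDataset,
                        cohort_normal: CohortDataset, seed: int = 0,
                        profile: str = "quick",
                        pre_cfg: PreprocessConfig = None,
                        peak_cfg: PeakConfig = None,
                        out_dir=None) -> dict:
    """Deep- vs normal-breathing contrast via peak-frequency shifts.

    Per condition: gradient-spectrum peaks (respiration and pupil, direct
    per-subject detection), jackknife coherence peaks from leave-one-out
    subaverages, Wilcoxon signed-rank tests on all three peak sets, and the
    coherence-vs-surrogate cluster test."""
    if len(cohort_deep) != len(cohort_normal):
        raise ValueError("cohorts must have matched subjects")
    mism = [(a.subject_id, b.subject_id)
            for a, b in zip(cohort_deep, cohort_normal)
            if a.subject_id != b.subject_id]
    if mism:
        raise ValueError(f"unmatched subjects: {mism}")
    pre_cfg = pre_cfg or PreprocessConfig()
    peak_cfg = peak_cfg or PeakConfig()

    def condition_tables(cohort):
        resp_peaks, pupil_peaks, coh_spectra = [], [], []
        freqs = None
        for subject in cohort:
            clean = preprocess_recording(subject.respiration, subject.pupil,
                                         pre_cfg)
            g_r = gradient_spectrum(clean.respiration)
            g_p = gradient_spectrum(clean.pupil)
            resp_peaks.append(find_spectral_peak(g_r, peak_cfg))
            pupil_peaks.append(find_spectral_peak(g_p, peak_cfg))
            r_spec, _ = multitaper_spectrum(clean.respiration)
            p_spec, _ = multitaper_spectrum(clean.pupil)
            coh = coherence(r_spec, p_spec)
            freqs = coh.freqs
            coh_spectra.append(coh.msc)
        coh_spectra = np.array(coh_spectra)
        coh_peaks = jackknife_peaks(coh_spectra, freqs, peak_cfg)
        return {
            "resp_peak_hz": _peak_freqs(resp_peaks),
            "pupil_peak_hz": _peak_freqs(pupil_peaks),
            "coherence_peak_hz": _peak_freqs(coh_peaks),
            "coherence_msc": coh_spectra,
            "freqs": freqs,
        }

    deep = condition_tables(cohort_deep)
    normal = condition_tables(cohort_normal)

    def paired_wilcoxon(key):
        a, b = deep[key], normal[key]
        keep = np.isfinite(a) & np.isfinite(b)
        z, p = wilcoxon_signed_rank(a[keep], b[keep])
        return {"z": z, "p": p, "n": int(keep.sum()),
                "mean_deep": float(np.nanmean(a)),
                "mean_normal": float(np.nanmean(b))}

    bundle = _new_bundle("breathing_modes", seed, profile, pre_cfg=pre_cfg,
                         peak_cfg=peak_cfg)
    bundle.update({
        "deep": deep,
        "normal": normal,
        "wilcoxon_resp": paired_wilcoxon("resp_peak_hz"),
        "wilcoxon_pupil": paired_wilcoxon("pupil_peak_hz"),
        "wilcoxon_coherence": paired_wilcoxon("coherence_peak_hz"),
        "coherence_vs_surrogate_deep": coherence_vs_surrogate(
            cohort_deep, seed, profile, pre_cfg),
        "coherence_vs_surrogate_normal": coherence_vs_surrogate(
            cohort_normal, seed + 1, profile, pre_cfg),
    })
    return _maybe_write(bundle, out_dir)


def run_rest_vs_task(cohort_rest: CohortDataset, cohort_task: CohortDataset,
                     seed: int = 0, profile: str = "quick",
                     pre_cfg: PreprocessConfig = None,
                     out_dir=None) -> dict:
    """Rest vs task contrast: paired cluster tests on respiration power,
    pupil power and log coherence.  Recordings of unequal length share one
    grid through the 600 s zero-padding rule."""
    if len(cohort_rest) != len(cohort_task):
        raise ValueError("cohorts must have matched subjects")
    pre_cfg = pre_cfg or PreprocessConfig()
    cluster_cfg = _cluster_cfg(profile)

    def tables(cohort):
        rp, pp, cl = [], [], []
        freqs = None
        for subject in cohort:
            clean = preprocess_recording(subject.respiration, subject.pupil,
                                         pre_cfg)
            r_spec, r_pow = multitaper_spectrum(clean.respiration)
            p_spec, p_pow = multitaper_spectrum(clean.pupil)
            coh = coherence(r_spec, p_spec)
            freqs = coh.freqs
            rp.append(r_pow.power_db)
            pp.append(p_pow.power_db)
            cl.append(coh.log_msc)
        return np.array(rp), np.array(pp), np.array(cl), freqs

    r_rest, p_rest, c_rest, freqs = tables(cohort_rest)
    r_task, p_task, c_task, _ = tables(cohort_task)
    bundle = _new_bundle("rest_vs_task", seed, profile, pre_cfg=pre_cfg,
                         cluster_cfg=cluster_cfg)
    bundle.update({
        "freqs": freqs,
        "respiration_contrast": cluster_perm_paired(r_rest, r_task,
                                                    cluster_cfg, seed=seed),
        "pupil_contrast": cluster_perm_paired(p_rest, p_task, cluster_cfg,
                                              seed=seed + 1),
        "coherence_contrast": cluster_perm_paired(c_rest, c_task, cluster_cfg,
                                                  seed=seed + 2),
        "mean_log_msc_rest": c_rest.mean(axis=0),
        "mean_log_msc_task": c_task.mean(axis=0),
    })
    return _maybe_write(bundle, out_dir)


def run_blocks_control(block_cohorts, seed: int = 0, profile: str = "quick",
                       pre_cfg: PreprocessConfig = None,
                       out_dir=None) -> dict:
    """Time-on-task control: regression cluster tests of respiration power,
    pupil power and coherence across the six ordered task blocks."""
    if len(block_cohorts) != 6:
        raise ValueError(f"expected 6 block cohorts, got {len(block_cohorts)}")
    n_sub = len(block_cohorts[0])
    if any(len(c) != n_sub for c in block_cohorts):
        raise ValueError("all blocks must contain the same subjects")
    pre_cfg = pre_cfg or PreprocessConfig()
    cluster_cfg = _cluster_cfg(profile)
    rp = [[] for _ in range(n_sub)]
    pp = [[] for _ in range(n_sub)]
    cl = [[] for _ in range(n_sub)]
    freqs = None
    for cohort in block_cohorts:
        for i, subject in enumerate(cohort):
            clean = preprocess_recording(subject.respiration, subject.pupil,
                                         pre_cfg)
            r_spec, r_pow = multitaper_spectrum(clean.respiration)
            p_spec, p_pow = multitaper_spectrum(clean.pupil)
            coh = coherence(r_spec, p_spec)
            freqs = coh.freqs
            rp[i].append(r_pow.power_db)
            pp[i].append(p_pow.power_db)
            cl[i].append(coh.log_msc)
    bundle = _new_bundle("blocks_control", seed, profile, pre_cfg=pre_cfg,
                         cluster_cfg=cluster_cfg)
    bundle.update({
        "freqs": freqs,
        "respiration_trend": cluster_perm_regression(np.array(rp),
                                                     cluster_cfg, seed=seed),
        "pupil_trend": cluster_perm_regression(np.array(pp), cluster_cfg,
                                               seed=seed + 1),
        "coherence_trend": cluster_perm_regression(np.array(cl), cluster_cfg,
                                                   seed=seed + 2),
    })
    return _maybe_write(bundle, out_dir)


def run_raw_pupil_control(cohort: CohortDataset, seed: int = 0,
                          profile: str = "quick",
                          pre_cfg: PreprocessConfig = None,
                          out_dir=None) -> dict:
    """Preprocessing control: the coherence branch re-run on raw pupil
    traces (blink interpolation and response removal skipped; filtering and
    z-scoring retained), plus the cleaned-vs-raw paired comparison."""
    from dataclasses import replace

    pre_cfg = pre_cfg or PreprocessConfig()
    raw_cfg = replace(pre_cfg, skip_pupil_cleaning=True)
    cluster_cfg = _cluster_cfg(profile)
    cleaned = coherence_vs_surrogate(cohort, seed, profile, pre_cfg,
                                     cluster_cfg=cluster_cfg)
    raw = coherence_vs_surrogate(cohort, seed, profile, raw_cfg,
                                 cluster_cfg=cluster_cfg)
    bundle = _new_bundle("raw_pupil_control", seed, profile, pre_cfg=pre_cfg,
                         cluster_cfg=cluster_cfg)
    bundle.update({
        "cleaned": cleaned,
        "raw": raw,
        "cleaned_vs_raw": cluster_perm_paired(
            cleaned["log_msc"], raw["log_msc"], cluster_cfg, seed=seed + 5),
    })
    return _maybe_write(bundle, out_dir)


# ---------------------------------------------------------------------------
# bundle plumbing
# ---------------------------------------------------------------------------

def _config_echo(**cfgs) -> dict:
    return {name: asdict(cfg) for name, cfg in cfgs.items() if cfg is not None}


def _new_bundle(name: str, seed: int, profile: str, **cfgs) -> dict:
    echo = _config_echo(**cfgs)
    blob = json.dumps(echo, sort_keys=True, default=str).encode()
    return {
        "analysis": name,
        "seed": int(seed),
        "profile": profile,
        "n_permutations": PROFILES[profile],
        "config": echo,
        "config_hash": hashlib.md5(blob).hexdigest(),
    }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonify({f: getattr(obj, f) for f in obj.__dataclass_fields__})
    return obj


def write_bundle(bundle: dict, out_dir) -> Path:
    """Serialize a results bundle to ``<out_dir>/<analysis>.json``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / f"{bundle['analysis']}.json"
    path.write_text(json.dumps(_jsonify(bundle), indent=1))
    return path


def _maybe_write(bundle: dict, out_dir):
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle
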