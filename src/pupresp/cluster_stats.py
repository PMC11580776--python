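"""Group-level nonparametric inference.

Cluster-based permutation tests control the family-wise error of spectrum-
wide contrasts: per-bin dependent-sample t (or per-subject regression-t
across ordered windows), clustering of suprathreshold bins along the
frequency axis, cluster mass = summed t, and a permutation null of maximal
cluster mass from within-subject sign flips (or window-order shuffles).  The
observed data counts toward the null (+1 convention), so the minimal
attainable p is 1/(n_permutations + 1); when the sign-flip group is no larger
than the requested permutation count the test switches to exhaustive
enumeration and the p-value is exact.  A relaxed two-dimensional criterion
(>= 5 adjacent suprathreshold cells, uncorrected) and the Wilcoxon
signed-rank test complete the toolbox.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "cluster_perm_paired",
    "cluster_perm_regression",
    "relaxed_cluster_2d",
    "wilcoxon_signed_rank",
]


@dataclass
class ClusterConfig:
    n_permutations: int = 5000
    alpha: float = 0.05
    cluster_forming_alpha: float = 0.05
    min_adjacent_2d: int = 5
    tail: str = "two-sided"

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        for a in (self.alpha, self.cluster_forming_alpha):
            if not 0 < a < 1:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class ClusterResult:
    clusters: list                 # dicts: bins, mass, p, sign
    per_bin_stat: np.ndarray
    null_distribution: np.ndarray  # permutation max |cluster mass| values
    config: ClusterConfig = None
    excluded_bins: list = field(default_factory=list)

    def significant(self, alpha: float = None) -> list:
        alpha = alpha if alpha is not None else (
            self.config.alpha if self.config else 0.05)
        return [c for c in self.clusters if c["p"] <= alpha]


def _t_one_sample(x: np.ndarray) -> np.ndarray:
    """One-sample t along axis 0, zero where the SE is zero."""
    n = x.shape[0]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.nan_to_num(t)


def _clusters_1d(t: np.ndarray, tcrit: float, valid: np.ndarray) -> list:
    """Contiguous suprathreshold runs, positive and negative separately."""
    out = []
    for sign in (1.0, -1.0):
        mask = (sign * t > tcrit) & valid
        if not mask.any():
            continue
        labels, n_lab = ndimage.label(mask)
        for lab in range(1, n_lab + 1):
            bins = np.flatnonzero(labels == lab)
            out.append({"bins": bins, "mass": float(t[bins].sum()),
                        "sign": int(sign)})
    return out


def _max_mass(t: np.ndarray, tcrit: float, valid: np.ndarray) -> float:
    """Maximal absolute cluster mass of one permutation sample (0 if none)."""
    best = 0.0
    for sign in (1.0, -1.0):
        mask = (sign * t > tcrit) & valid
        if not mask.any():
            continue
        edges = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
        starts = np.flatnonzero(edges == 1)
        stops = np.flatnonzero(edges == -1)
        csum = np.concatenate(([0.0], np.cumsum(t)))
        masses = np.abs(csum[stops] - csum[starts])
        best = max(best, masses.max())
    return best


def _null_from_tmat(tmat: np.ndarray, tcrit: float, valid: np.ndarray
                    ) -> np.ndarray:
    return np.array([_max_mass(row, tcrit, valid) for row in tmat])


def _finalize(t_obs, tcrit, valid, null, exact: bool, n_eff: int,
              cfg: ClusterConfig) -> ClusterResult:
    clusters = _clusters_1d(t_obs, tcrit, valid)
    for c in clusters:
        ge = int(np.sum(null >= abs(c["mass"]) - 1e-12))
        if exact:
            c["p"] = ge / null.size
        else:
            c["p"] = (ge + 1) / (null.size + 1)
    clusters.sort(key=lambda c: abs(c["mass"]), reverse=True)
    return ClusterResult(clusters, t_obs, null, cfg,
                         excluded_bins=np.flatnonzero(~valid).tolist())


def cluster_perm_paired(a: np.ndarray, b: np.ndarray,
                        cfg: ClusterConfig = None, seed: int = 0
                        ) -> ClusterResult:
    """Paired cluster permutation test of two condition-spectra arrays.

    ``a`` and ``b`` are (n_subjects, n_bins) with matching subjects.  The
    null flips the sign of each subject's difference spectrum; with
    ``2**n_subjects <= n_permutations`` the full flip group is enumerated and
    the p-values are exact.
    """
    cfg = cfg or ClusterConfig()
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 2:
        raise ValueError("need matching (n_subjects >= 2, n_bins) arrays")
    d = a - b
    n, nb = d.shape
    valid = d.std(axis=0, ddof=1) > 0
    tcrit = stats.t.ppf(1.0 - cfg.cluster_forming_alpha / 2.0, n - 1)
    t_obs = _t_one_sample(d)

    ss = (d ** 2).sum(axis=0)  # invariant under sign flips
    exact = 2 ** n <= cfg.n_permutations
    if exact:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(cfg.n_permutations, n))
    mean = signs @ d / n
    var = (ss - n * mean ** 2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmat = mean / np.sqrt(var / n)
    tmat = np.nan_to_num(tmat)
    null = _null_from_tmat(tmat, tcrit, valid)
    return _finalize(t_obs, tcrit, valid, null, exact, n, cfg)


def cluster_perm_regression(windowed: np.ndarray, cfg: ClusterConfig = None,
                            seed: int = 0) -> ClusterResult:
    """Cluster permutation test for monotonic trends across ordered windows.

    ``windowed`` is (n_subjects, n_windows, n_bins).  Per subject and bin a
    least-squares slope of the value on the window index is computed; the
    group per-bin statistic is the one-sample t of those slopes.  The null
    shuffles the window order independently within each subject
    (exchangeable under the no-trend hypothesis).
    """
    cfg = cfg or ClusterConfig()
    x = np.asarray(windowed, float)
    if x.ndim != 3 or x.shape[1] < 3:
        raise ValueError("need (n_subjects, n_windows >= 3, n_bins)")
    n, nw, nb = x.shape
    w = np.arange(nw) - (nw - 1) / 2.0
    w = w / (w ** 2).sum()
    slopes = np.einsum("w,swb->sb", w, x)
    t_obs = _t_one_sample(slopes)
    valid = slopes.std(axis=0, ddof=1) > 0
    tcrit = stats.t.ppf(1.0 - cfg.cluster_forming_alpha / 2.0, n - 1)

    rng = np.random.default_rng(seed)
    null = np.empty(cfg.n_permutations)
    for p in range(cfg.n_permutations):
        wp = np.stack([w[rng.permutation(nw)] for _ in range(n)])
        sl = np.einsum("sw,swb->sb", wp, x)
        null[p] = _max_mass(_t_one_sample(sl), tcrit, valid)
    return _finalize(t_obs, tcrit, valid, null, False, n, cfg)


def relaxed_cluster_2d(stat_map: np.ndarray, df: int,
                       cfg: ClusterConfig = None) -> list:
    """Relaxed two-dimensional cluster criterion on a t map.

    Cells beyond the two-sided uncorrected threshold are grouped under
    4-connectivity; components of at least ``min_adjacent_2d`` cells are
    retained.  No permutation correction is applied -- this is the explicit
    uncorrected fallback, used when the corrected 2-D test finds nothing.
    """
    cfg = cfg or ClusterConfig()
    m = np.asarray(stat_map, float)
    if not np.all(np.isfinite(m)):
        raise ValueError("stat map must be finite")
    tcrit = stats.t.ppf(1.0 - cfg.cluster_forming_alpha / 2.0, df)
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    out = []
    for sign in (1.0, -1.0):
        mask = sign * m > tcrit
        labels, n_lab = ndimage.label(mask, structure=structure)
        for lab in range(1, n_lab + 1):
            cells = np.argwhere(labels == lab)
            if cells.shape[0] >= cfg.min_adjacent_2d:
                out.append({
                    "cells": [tuple(c) for c in cells],
                    "mass": float(m[labels == lab].sum()),
                    "sign": int(sign),
                })
    out.sort(key=lambda c: abs(c["mass"]), reverse=True)
    return out


def wilcoxon_signed_rank(a, b, method: str = "auto") -> tuple:
    """Wilcoxon signed-rank test for paired samples; returns ``(Z, p)``.

    Zero differences are dropped, ties get mid-ranks.  The p-value is exact
    (full enumeration) for fewer than 20 non-zero pairs without ties, and a
    normal approximation with continuity correction otherwise.  Z is signed:
    positive when ``a`` tends to exceed ``b``.
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 0.0, 1.0
    corr = 0.5 * np.sign(w_pos - mu)
    z = (w_pos - mu - corr) / np.sqrt(var)
    has_ties = np.any(tie_counts > 1)
    if method == "auto":
        method = "exact" if (n < 20 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         method=method, alternative="two-sided")
    return float(z), float(res.pvalue)
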