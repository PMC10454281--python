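"""Cluster-based permutation tests over channel x frequency x time.

Pointwise t statistics are thresholded at the two-sided cluster-forming alpha
(default 0.001); supra-threshold cells of equal sign are clustered through
adjacency in time (+-1 sample), frequency (+-1 grid step) and space (the
electrode adjacency structure); the cluster statistic is the summed t (mass),
and its significance is the Monte-Carlo p-value against the permutation null
of the maximum absolute cluster mass (sign flips of within-subject differences
for the paired test, group relabellings for the independent test):

    p = (1 + #{null >= observed}) / (n_permutations + 1).

A scalar permutation test on per-subject graph metrics is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import sparse, stats

from .layout import AdjacencyStructure


@dataclass
class ClusterTestConfig:
    cluster_alpha: float = 0.001
    n_permutations: int = 10000
    alpha: float = 0.05
    adjacency: AdjacencyStructure | None = None
    seed: int = 0
    time_window_ms: tuple = (-150.0, 150.0)
    freq_range_hz: tuple = (0.5, 70.0)

    def __post_init__(self) -> None:
        if not (0 < self.cluster_alpha < 1):
            raise ValueError("cluster alpha must be in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")


@dataclass
class Cluster:
    cells: np.ndarray  # (k, 3) array of (channel, freq, time) indices
    sign: int
    mass: float
    p: float = np.nan


@dataclass
class ClusterTestResult:
    clusters: list
    tmap: np.ndarray
    null_max_mass: np.ndarray
    config: ClusterTestConfig
    df: int

    def significant(self) -> list:
        return [c for c in self.clusters if c.p <= self.config.alpha]


def _adj_pairs(adjacency: AdjacencyStructure | None, n_channels: int) -> np.ndarray:
    if adjacency is None:
        return np.empty((0, 2), dtype=int)
    if adjacency.n_channels != n_channels:
        raise ValueError("adjacency channel count does not match the data")
    return adjacency.pairs()


def _find_clusters(tmap: np.ndarray, thresh: float, adj_pairs: np.ndarray) -> list:
    """Signed supra-threshold clusters of a (C, F, T) t-map."""
    C, F, T = tmap.shape
    clusters = []
    for sign in (1, -1):
        mask = (sign * tmap) > thresh
        k = int(mask.sum())
        if k == 0:
            continue
        ids = np.full(tmap.shape, -1, dtype=np.int64)
        ids[mask] = np.arange(k)
        edges_u, edges_v = [], []
        if F > 1:
            both = mask[:, :-1, :] & mask[:, 1:, :]
            edges_u.append(ids[:, :-1, :][both])
            edges_v.append(ids[:, 1:, :][both])
        if T > 1:
            both = mask[:, :, :-1] & mask[:, :, 1:]
            edges_u.append(ids[:, :, :-1][both])
            edges_v.append(ids[:, :, 1:][both])
        if adj_pairs.size:
            mi = mask[adj_pairs[:, 0]]
            both = mi & mask[adj_pairs[:, 1]]
            edges_u.append(ids[adj_pairs[:, 0]][both])
            edges_v.append(ids[adj_pairs[:, 1]][both])
        if edges_u:
            u = np.concatenate(edges_u)
            v = np.concatenate(edges_v)
        else:
            u = v = np.empty(0, dtype=np.int64)
        graph = sparse.coo_matrix((np.ones(u.size), (u, v)), shape=(k, k))
        n_comp, labels = sparse.csgraph.connected_components(graph, directed=False)
        cell_idx = np.argwhere(mask)  # (k, 3) in id order
        tvals = tmap[mask]
        for comp in range(n_comp):
            member = labels == comp
            clusters.append(Cluster(cells=cell_idx[member], sign=sign,
                                    mass=float(tvals[member].sum())))
    return clusters


def _max_mass(tmap: np.ndarray, thresh: float, adj_pairs: np.ndarray) -> float:
    cl = _find_clusters(tmap, thresh, adj_pairs)
    return max((abs(c.mass) for c in cl), default=0.0)


def _paired_t(diff_flat: np.ndarray) -> np.ndarray:
    n = diff_flat.shape[0]
    mean = diff_flat.mean(axis=0)
    var = diff_flat.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / np.sqrt(var / n)
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def paired_cluster_test(values: np.ndarray, baseline: np.ndarray,
                        cfg: ClusterTestConfig) -> ClusterTestResult:
    """Within-group cluster test of (values - baseline), subjects first axis.

    ``values`` and ``baseline`` are (subjects, channels, freqs, times); the
    null distribution is built from random sign flips of the subject-level
    difference maps.
    """
    values = np.asarray(values, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    if values.shape != baseline.shape:
        raise ValueError("values and baseline must share a shape")
    if values.ndim != 4 or values.shape[0] < 2:
        raise ValueError("need (subjects, channels, freqs, times) with >= 2 subjects")
    n, C, F, T = values.shape
    adj_pairs = _adj_pairs(cfg.adjacency, C)
    df = n - 1
    thresh = stats.t.ppf(1 - cfg.cluster_alpha / 2, df)
    diff = (values - baseline).reshape(n, -1)

    tmap = _paired_t(diff).reshape(C, F, T)
    clusters = _find_clusters(tmap, thresh, adj_pairs)

    rng = np.random.default_rng(cfg.seed)
    ssq = (diff**2).sum(axis=0)  # invariant under sign flips
    null = np.empty(cfg.n_permutations)
    chunk = max(1, min(256, int(2e8 // max(diff.size, 1))))
    done = 0
    while done < cfg.n_permutations:
        p = min(chunk, cfg.n_permutations - done)
        signs = rng.integers(0, 2, size=(p, n)) * 2.0 - 1.0
        mean_p = signs @ diff / n
        var_p = (ssq / n - mean_p**2) * (n / (n - 1))
        with np.errstate(invalid="ignore", divide="ignore"):
            t_p = mean_p / np.sqrt(var_p / n)
        t_p = np.nan_to_num(t_p, nan=0.0, posinf=0.0, neginf=0.0)
        for i in range(p):
            null[done + i] = _max_mass(t_p[i].reshape(C, F, T), thresh, adj_pairs)
        done += p
    for c in clusters:
        c.p = float((1 + np.sum(null >= abs(c.mass) - 1e-12)) / (cfg.n_permutations + 1))
    return ClusterTestResult(clusters=clusters, tmap=tmap, null_max_mass=null, config=cfg, df=df)


def independent_cluster_test(group_a: np.ndarray, group_b: np.ndarray,
                             cfg: ClusterTestConfig) -> ClusterTestResult:
    """Between-group cluster test (pooled-variance two-sample t).

    The null distribution is built by randomly reassigning subjects to groups,
    preserving group sizes.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.ndim != 4 or b.ndim != 4 or a.shape[1:] != b.shape[1:]:
        raise ValueError("groups must be (subjects, channels, freqs, times) with matching grids")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 subjects per group")
    _, C, F, T = a.shape
    adj_pairs = _adj_pairs(cfg.adjacency, C)
    df = na + nb - 2
    thresh = stats.t.ppf(1 - cfg.cluster_alpha / 2, df)
    X = np.concatenate([a, b], axis=0).reshape(na + nb, -1)
    Xsq = X**2
    total = X.sum(axis=0)
    total_sq = Xsq.sum(axis=0)

    def t_from_sel(sel):
        # sel: (p, n) 0/1 group-a membership
        sum_a = sel @ X
        sumsq_a = sel @ Xsq
        ma = sum_a / na
        mb = (total - sum_a) / nb
        va = sumsq_a - na * ma**2
        vb = (total_sq - sumsq_a) - nb * mb**2
        s2 = (va + vb) / df
        with np.errstate(invalid="ignore", divide="ignore"):
            t = (ma - mb) / np.sqrt(s2 * (1.0 / na + 1.0 / nb))
        return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)

    sel_obs = np.zeros((1, na + nb))
    sel_obs[0, :na] = 1.0
    tmap = t_from_sel(sel_obs)[0].reshape(C, F, T)
    clusters = _find_clusters(tmap, thresh, adj_pairs)

    rng = np.random.default_rng(cfg.seed)
    null = np.empty(cfg.n_permutations)
    chunk = max(1, min(256, int(2e8 // max(X.size, 1))))
    done = 0
    while done < cfg.n_permutations:
        p = min(chunk, cfg.n_permutations - done)
        sel = np.zeros((p, na + nb))
        for i in range(p):
            sel[i, rng.permutation(na + nb)[:na]] = 1.0
        t_p = t_from_sel(sel)
        for i in range(p):
            null[done + i] = _max_mass(t_p[i].reshape(C, F, T), thresh, adj_pairs)
        done += p
    for c in clusters:
        c.p = float((1 + np.sum(null >= abs(c.mass) - 1e-12)) / (cfg.n_permutations + 1))
    return ClusterTestResult(clusters=clusters, tmap=tmap, null_max_mass=null, config=cfg, df=df)


@dataclass
class PermutationTestResult:
    p: float
    observed: float
    n_permutations: int
    exhaustive: bool


def permutation_mean_test(metric_a, metric_b, n_perm: int = 10000, seed: int = 0,
                          exhaustive: bool = False) -> PermutationTestResult:
    """Two-sided permutation test on the absolute group-mean difference.

    Monte-Carlo p is (1 + #{null >= observed}) / (n_perm + 1); with
    ``exhaustive=True`` all C(na+nb, na) assignments are enumerated and p is
    the exact tail fraction.
    """
    a = np.asarray(metric_a, dtype=np.float64).ravel()
    b = np.asarray(metric_b, dtype=np.float64).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    pooled = np.concatenate([a, b])
    na = a.size
    obs = abs(a.mean() - b.mean())
    tol = 1e-12 * max(1.0, obs)
    if exhaustive:
        total = 0
        count = 0
        idx_all = set(range(pooled.size))
        for comb in combinations(range(pooled.size), na):
            sel = list(comb)
            rest = list(idx_all - set(comb))
            d = abs(pooled[sel].mean() - pooled[rest].mean())
            count += d >= obs - tol
            total += 1
        return PermutationTestResult(p=count / total, observed=obs,
                                     n_permutations=total, exhaustive=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = abs(perm[:na].mean() - perm[na:].mean())
        count += d >= obs - tol
    return PermutationTestResult(p=(1 + count) / (n_perm + 1), observed=obs,
                                 n_permutations=n_perm, exhaustive=False)
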