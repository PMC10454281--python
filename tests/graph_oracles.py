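"""Brute-force graph-metric oracles for small weighted graphs.

Shortest paths are found by exhaustive enumeration of simple paths, fully
independent of the sparse-graph routines used by the implementation.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_shortest_path(lengths: np.ndarray, i: int, j: int) -> float:
    """Minimum total length over all simple paths from i to j."""
    n = lengths.shape[0]
    others = [k for k in range(n) if k not in (i, j)]
    best = lengths[i, j]
    for r in range(1, n - 1):
        for mid in permutations(others, r):
            nodes = [i, *mid, j]
            total = sum(lengths[a, b] for a, b in zip(nodes[:-1], nodes[1:]))
            best = min(best, total)
    return best


def brute_global_efficiency(W: np.ndarray) -> float:
    n = W.shape[0]
    L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    acc = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = brute_shortest_path(L, i, j)
            if np.isfinite(d) and d > 0:
                acc += 1.0 / d
    return acc / (n * (n - 1))


def brute_local_efficiency(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    out = np.zeros(n)
    for u in range(n):
        nb = [j for j in range(n) if W[u, j] > 0]
        k = len(nb)
        if k < 2:
            continue
        sub = W[np.ix_(nb, nb)]
        L = np.where(sub > 0, (1.0 / np.where(sub > 0, sub, 1.0)) ** (1 / 3), np.inf)
        np.fill_diagonal(L, 0.0)
        acc = 0.0
        for a in range(k):
            for b in range(k):
                if a == b:
                    continue
                d = brute_shortest_path(L, a, b)
                if np.isfinite(d) and d > 0:
                    acc += (W[u, nb[a]] * W[u, nb[b]]) ** (1 / 3) / d
        out[u] = acc / (k * (k - 1))
    return out
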