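"""dwPLI functional connectivity and weighted graph metrics.

The debiased weighted phase lag index is computed per (frequency, time) cell
from the imaginary part of the trial cross-spectrum I_k = Im(F_k(a) conj(F_k(b))):

    dwPLI = [ (sum_k I_k)^2 - sum_k I_k^2 ] / [ (sum_k |I_k|)^2 - sum_k I_k^2 ]

then averaged over the band x window cells.  The estimator is insensitive to
zero-lag (volume-conducted) coupling and debiased for finite trial counts; it
can be negative at small n, so cells are optionally clamped to 0 after
averaging when the matrix feeds nonnegative-weight graph metrics.

Graph metrics follow the weighted Brain-Connectivity-Toolbox definitions with
the connection-length map L_ij = 1 / W_ij.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .timefreq import TFDecomposition


@dataclass
class BandConnectivity:
    """Symmetric channels x channels dwPLI weight matrix for one band."""

    W: np.ndarray
    band: str
    window_ms: tuple
    n_trials: int
    ch_names: list[str]
    clamped: bool = True
    W_raw: np.ndarray | None = None  # signed matrix before clamping

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=np.float64)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if np.any(np.abs(np.diag(W)) > 1e-12):
            raise ValueError("W must have zero diagonal")
        if self.clamped and (W.min() < -1e-12 or W.max() > 1 + 1e-9):
            raise ValueError("clamped weights must lie in [0, 1]")
        self.W = W

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


def dwpli_cells(coeffs: np.ndarray) -> np.ndarray:
    """dwPLI per cell from coefficients shaped (trials, channels, cells).

    Returns (channels, channels, cells) with zero diagonal; cells whose
    denominator vanishes (all imaginary cross-spectra zero) are 0 by
    convention.
    """
    F = np.asarray(coeffs)
    if F.ndim != 3:
        raise ValueError("coeffs must be (trials, channels, cells)")
    n = F.shape[0]
    if n < 2:
        raise ValueError("dwPLI needs at least 2 trials")
    A, B = F.real, F.imag
    # I_k[a, b] = Im(F_a conj(F_b)) = B_a A_b - A_a B_b, per trial and cell
    I = np.einsum("kac,kbc->kabc", B, A) - np.einsum("kac,kbc->kabc", A, B)
    s1 = I.sum(axis=0)
    s2 = (I**2).sum(axis=0)
    sa = np.abs(I).sum(axis=0)
    num = s1**2 - s2
    den = sa**2 - s2
    with np.errstate(invalid="ignore", divide="ignore"):
        val = np.where(den > 1e-300, num / np.maximum(den, 1e-300), 0.0)
    idx = np.arange(F.shape[1])
    val[idx, idx, :] = 0.0
    return val


def dwpli_from_coeffs(coeffs: np.ndarray, clamp_negative: bool = True,
                      cell_chunk: int = 64) -> tuple[np.ndarray, np.ndarray]:
    """Band/window-averaged dwPLI from (trials, channels, cells) coefficients.

    Returns ``(W, W_raw)``: the graph-ready matrix (clamped at 0 if requested)
    and the signed cell-averaged matrix.  Cells are processed in chunks to
    bound memory at high channel counts.
    """
    F = np.asarray(coeffs)
    n_cells = F.shape[2]
    acc = np.zeros((F.shape[1], F.shape[1]))
    for c0 in range(0, n_cells, cell_chunk):
        acc += dwpli_cells(F[:, :, c0:c0 + cell_chunk]).sum(axis=2)
    W_raw = acc / n_cells
    W_raw = (W_raw + W_raw.T) / 2.0
    np.fill_diagonal(W_raw, 0.0)
    W = np.clip(W_raw, 0.0, None) if clamp_negative else W_raw
    return W, W_raw


def dwpli_matrix(tf: TFDecomposition, band: str,
                 window_ms: tuple[float, float] = (-150.0, 150.0),
                 clamp_negative: bool = True) -> BandConnectivity:
    """Trial-ensemble dwPLI association matrix for one band and time window."""
    fidx = tf.grid.band_indices(band)
    tmask = tf.time_mask(window_ms)
    if not tmask.any():
        raise ValueError("window contains no samples")
    F = tf.coeffs[:, :, fidx][:, :, :, tmask]
    F = F.reshape(F.shape[0], F.shape[1], -1)
    W, W_raw = dwpli_from_coeffs(F, clamp_negative=clamp_negative)
    return BandConnectivity(W=W, band=band, window_ms=tuple(window_ms), n_trials=tf.n_trials,
                            ch_names=list(tf.ch_names), clamped=clamp_negative, W_raw=W_raw)


def node_strength(conn: BandConnectivity | np.ndarray) -> np.ndarray:
    """s_i = sum_j W_ij."""
    W = conn.W if isinstance(conn, BandConnectivity) else np.asarray(conn, dtype=float)
    return W.sum(axis=1)


def _length_matrix(W: np.ndarray, transform=lambda x: x) -> np.ndarray:
    L = np.full_like(W, np.inf, dtype=np.float64)
    nz = W > 0
    L[nz] = transform(1.0 / W[nz])
    np.fill_diagonal(L, 0.0)
    return L


def global_efficiency(conn: BandConnectivity | np.ndarray) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Weights map to lengths 1/W; unreachable pairs contribute 0; a fully
    disconnected graph has efficiency 0.
    """
    W = conn.W if isinstance(conn, BandConnectivity) else np.asarray(conn, dtype=float)
    n = W.shape[0]
    if n < 2:
        return 0.0
    d = shortest_path(_length_matrix(W), method="D", directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(conn: BandConnectivity | np.ndarray) -> np.ndarray:
    """Weighted local efficiency per node (Brain-Connectivity-Toolbox form).

    For node u with neighbourhood N(u) = {j : W_uj > 0}, shortest paths d* are
    computed within the N(u) subgraph on cube-root-transformed lengths
    (1/w)^(1/3), and

        E_loc(u) = sum_{j != h in N(u)} (W_uj W_uh)^(1/3) / d*_jh / (k_u (k_u - 1)).

    Nodes with fewer than 2 neighbours score 0.
    """
    W = conn.W if isinstance(conn, BandConnectivity) else np.asarray(conn, dtype=float)
    n = W.shape[0]
    out = np.zeros(n)
    for u in range(n):
        nb = np.flatnonzero(W[u] > 0)
        k = nb.size
        if k < 2:
            continue
        sub = W[np.ix_(nb, nb)]
        d = shortest_path(_length_matrix(sub, transform=np.cbrt), method="D", directed=False)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        np.fill_diagonal(inv, 0.0)
        sw = np.cbrt(W[u, nb])
        out[u] = float((np.outer(sw, sw) * inv).sum() / (k * (k - 1)))
    return out


def proportional_threshold(conn: BandConnectivity, proportion: float) -> BandConnectivity:
    """Keep the strongest fraction of off-diagonal edges, zero the rest.

    The kept count is round-half-up of proportion * n(n-1)/2; ties at the
    cutoff are broken deterministically by (lower channel index, lower partner
    index).
    """
    if not (0 < proportion <= 1):
        raise ValueError("proportion must be in (0, 1]")
    W = conn.W
    n = W.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    n_edges = iu.size
    keep = int(np.floor(proportion * n_edges + 0.5))
    order = np.lexsort((ju, iu, -W[iu, ju]))  # weight desc, then (i, j) asc
    kept = order[:keep]
    Wt = np.zeros_like(W)
    Wt[iu[kept], ju[kept]] = W[iu[kept], ju[kept]]
    Wt = Wt + Wt.T
    return BandConnectivity(W=Wt, band=conn.band, window_ms=conn.window_ms,
                            n_trials=conn.n_trials, ch_names=list(conn.ch_names),
                            clamped=conn.clamped, W_raw=conn.W_raw)
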