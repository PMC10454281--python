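"""Spherical-spline interpolation and surface-Laplacian (CSD) transform.

Perrin-style spherical splines on the unit sphere: the interpolation kernel

    g(x) = (1/4pi) * sum_{n=1..N} (2n+1) / (n(n+1))^m * P_n(x)

and the Laplacian kernel h(x) with exponent m-1, where P_n are Legendre
polynomials and x = cos(theta) is the cosine of the inter-electrode angle.
Defaults follow common scalp-CSD practice: spline flexibility m = 4, smoothing
lambda = 1e-5, Legendre series truncated at degree N = 10, unit sphere radius.
CSD output is in uV/m^2 up to the (unit) head-radius scale factor; the
absolute scale does not affect ERSP, ITC or dwPLI downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre

from .epochs import EpochedEEG
from .layout import ElectrodeLayout


def _kernel_coeffs(m: float, max_degree: int) -> np.ndarray:
    n = np.arange(1, max_degree + 1, dtype=np.float64)
    c = np.zeros(max_degree + 1)
    c[1:] = (2 * n + 1) / (n * (n + 1)) ** m / (4 * np.pi)
    return c


def spline_kernels(cosang: np.ndarray, m: float, max_degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the interpolation (g) and Laplacian (h) kernels at cos(theta).

    Uses numpy's Clenshaw-recurrence Legendre evaluation for stability.
    """
    x = np.clip(np.asarray(cosang, dtype=np.float64), -1.0, 1.0)
    g = legendre.legval(x, _kernel_coeffs(m, max_degree))
    h = legendre.legval(x, _kernel_coeffs(m - 1, max_degree))
    return g, h


@dataclass
class SplineOperator:
    """Precomputed spline matrices for one electrode layout."""

    G: np.ndarray  # interpolation kernel matrix (E x E)
    H: np.ndarray  # Laplacian kernel matrix (E x E)
    m: float
    lam: float
    max_degree: int
    labels: list[str]

    _solver: np.ndarray | None = None  # inverse of the augmented Perrin system

    def solver(self) -> np.ndarray:
        """Inverse of [[G + lam*I, 1], [1^T, 0]]; cached."""
        if self._solver is None:
            e = len(self.labels)
            A = np.zeros((e + 1, e + 1))
            A[:e, :e] = self.G + self.lam * np.eye(e)
            A[:e, e] = 1.0
            A[e, :e] = 1.0
            try:
                self._solver = np.linalg.inv(A)
            except np.linalg.LinAlgError:
                warnings.warn("singular spline system; using pseudo-inverse")
                self._solver = np.linalg.pinv(A)
        return self._solver

    def csd_transform(self) -> np.ndarray:
        """Matrix T with CSD = T @ potentials, identical for every sample."""
        e = len(self.labels)
        return self.H @ self.solver()[:e, :e]


def build_spline_operator(layout: ElectrodeLayout, m: int = 4, lam: float = 1e-5,
                          max_degree: int = 10) -> SplineOperator:
    """Spline kernel matrices for ``layout`` (G for interpolation, H for CSD)."""
    if m < 2:
        raise ValueError("spline flexibility m must be >= 2")
    if lam < 0:
        raise ValueError("smoothing constant must be >= 0")
    if max_degree < 1:
        raise ValueError("max Legendre degree must be >= 1")
    pos = layout.positions
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    off = ~np.eye(len(pos), dtype=bool)
    if np.any(cosang[off] > 1 - 1e-12):
        warnings.warn("coincident electrodes in layout; kernels remain finite (truncated series)")
    G, H = spline_kernels(cosang, m, max_degree)
    return SplineOperator(G=G, H=H, m=float(m), lam=float(lam),
                          max_degree=int(max_degree), labels=list(layout.labels))


def fit_spline(values: np.ndarray, op: SplineOperator) -> tuple[float, np.ndarray]:
    """Solve the Perrin system (G + lam*I)c + c0*1 = v with sum(c) = 0.

    Returns ``(c0, c)``. ``values`` may be (E,) or (E, k) for k simultaneous
    fits (then c0 is a length-k vector and c is (E, k)).
    """
    v = np.asarray(values, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    e = len(op.labels)
    if v.shape[0] != e:
        raise ValueError("values length must match operator layout")
    rhs = np.concatenate([v, np.zeros((1,) + v.shape[1:])], axis=0)
    sol = op.solver() @ rhs
    return sol[e], sol[:e]


def surface_laplacian(ep: EpochedEEG, op: SplineOperator) -> EpochedEEG:
    """Apply the spherical-spline surface Laplacian to every trial and sample.

    The composite transform matrix is precomputed once and applied samplewise;
    the output is flagged as CSD.
    """
    if list(ep.ch_names) != list(op.labels):
        raise ValueError("epochs and spline operator have different channel sets")
    T = op.csd_transform()
    data = np.einsum("ij,kjt->kit", T, ep.data)
    return ep.copy_with(data=data, is_csd=True)


def interpolation_matrix(layout: ElectrodeLayout, good: list[int], bad: list[int],
                         m: int = 4, lam: float = 1e-5, max_degree: int = 10) -> np.ndarray:
    """Matrix mapping good-channel values to spherical-spline estimates at bad
    channel positions: ``bad_values = M @ good_values``."""
    sub = ElectrodeLayout(labels=[layout.labels[i] for i in good],
                          positions=layout.positions[good])
    op = build_spline_operator(sub, m=m, lam=lam, max_degree=max_degree)
    e = len(good)
    inv = op.solver()
    cos_bg = np.clip(layout.positions[bad] @ layout.positions[good].T, -1.0, 1.0)
    G_bg, _ = spline_kernels(cos_bg, m, max_degree)
    # value at r = c0 + sum_j c_j g(cos(r, r_j))
    return G_bg @ inv[:e, :e] + np.outer(np.ones(len(bad)), inv[e, :e])
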