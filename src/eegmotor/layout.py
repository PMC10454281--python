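"""Electrode layouts and spatial channel adjacency.

The reference montage is the 128-channel Biosemi ABC layout (labels A1..D32).
Positions are kept on the unit sphere; the spatial neighbourhood structure
used by the cluster statistics combines a Euclidean distance criterion with
Delaunay triangulation of the electrode positions, mirroring common practice
for scalp-level cluster tests.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np


class LayoutError(ValueError):
    pass


@dataclass
class ElectrodeLayout:
    """Named electrode positions normalized to the unit sphere."""

    labels: list[str]
    positions: np.ndarray  # (n, 3) unit vectors
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        if len(set(self.labels)) != len(self.labels):
            raise LayoutError("duplicate electrode labels")
        pos = np.asarray(self.positions, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] != len(self.labels):
            raise LayoutError("positions must be (n_labels, 3)")
        if not np.all(np.isfinite(pos)):
            raise LayoutError("non-numeric electrode coordinates")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms < 1e-12):
            raise LayoutError("zero-norm electrode position cannot be projected to the sphere")
        self.positions = pos / norms[:, None]

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels: list[str]) -> "ElectrodeLayout":
        idx = [self.index(l) for l in labels]
        return ElectrodeLayout(labels=list(labels), positions=self.positions[idx],
                               aliases={k: v for k, v in self.aliases.items() if k in labels})


@dataclass
class AdjacencyStructure:
    """Per-channel neighbour sets; symmetric and irreflexive by construction."""

    neighbors: list[set]

    def __post_init__(self) -> None:
        n = len(self.neighbors)
        self.neighbors = [set(int(j) for j in s) for s in self.neighbors]
        for i, s in enumerate(self.neighbors):
            if i in s:
                raise LayoutError("adjacency must be irreflexive")
            for j in s:
                if not (0 <= j < n):
                    raise LayoutError("neighbour index out of range")
                if i not in self.neighbors[j]:
                    raise LayoutError("adjacency must be symmetric")

    @property
    def n_channels(self) -> int:
        return len(self.neighbors)

    def as_matrix(self) -> np.ndarray:
        n = len(self.neighbors)
        m = np.zeros((n, n), dtype=bool)
        for i, s in enumerate(self.neighbors):
            for j in s:
                m[i, j] = True
        return m

    def pairs(self) -> np.ndarray:
        """(k, 2) array of i<j neighbour pairs."""
        out = [(i, j) for i, s in enumerate(self.neighbors) for j in s if i < j]
        return np.asarray(out, dtype=int).reshape(-1, 2)


def load_layout(path_or_buffer) -> ElectrodeLayout:
    """Read an electrode table (label, x, y, z; comma or whitespace separated).

    Positions are projected to the unit sphere.  Lines starting with ``#`` are
    ignored.
    """
    if hasattr(path_or_buffer, "read"):
        text = path_or_buffer.read()
    else:
        with open(path_or_buffer) as fh:
            text = fh.read()
    labels, rows = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 4:
            raise LayoutError(f"layout row needs label and x y z: {line!r}")
        if parts[0].lower() in {"label", "name"}:  # header row
            continue
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError as exc:
            raise LayoutError(f"non-numeric coordinate in row {line!r}") from exc
        labels.append(parts[0])
        rows.append(xyz)
    return ElectrodeLayout(labels=labels, positions=np.asarray(rows))


def _fit_sphere_center(pos: np.ndarray) -> np.ndarray:
    # linear least-squares sphere fit: |p - c|^2 = r^2
    A = np.hstack([2.0 * pos, np.ones((len(pos), 1))])
    b = (pos**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


def default_biosemi128() -> ElectrodeLayout:
    """The packaged default 128-channel Biosemi ABC layout (A1..D32).

    Built from the standard biosemi128 montage shipped with MNE, re-centred by
    a least-squares sphere fit and projected to the unit sphere.
    """
    import mne

    montage = mne.channels.make_standard_montage("biosemi128")
    ch_pos = montage.get_positions()["ch_pos"]
    labels = [f"{bank}{i}" for bank in "ABCD" for i in range(1, 33)]
    pos = np.asarray([ch_pos[l] for l in labels])
    pos = pos - _fit_sphere_center(pos)
    return ElectrodeLayout(labels=labels, positions=pos)


def _azimuthal_equidistant(pos: np.ndarray) -> np.ndarray:
    """Project unit-sphere points to 2D around the +z pole (vertex)."""
    z = np.clip(pos[:, 2], -1.0, 1.0)
    theta = np.arccos(z)  # polar angle = arc distance from the pole
    horiz = np.linalg.norm(pos[:, :2], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(horiz > 1e-12, pos[:, 0] / horiz, 1.0)
        uy = np.where(horiz > 1e-12, pos[:, 1] / horiz, 0.0)
    return np.column_stack([theta * ux, theta * uy])


def build_adjacency(
    layout: ElectrodeLayout,
    distance_threshold: float = 0.4,
    use_triangulation: bool = True,
) -> AdjacencyStructure:
    """Neighbour structure = distance pairs UNION Delaunay-triangulation edges.

    The distance criterion links electrodes closer than ``distance_threshold``
    (Euclidean, on the unit sphere); the triangulation criterion links edges of
    the Delaunay triangulation of the azimuthal-equidistant 2D projection.
    """
    if distance_threshold <= 0:
        raise LayoutError("distance threshold must be positive")
    pos = layout.positions
    n = layout.n_channels
    neighbors = [set() for _ in range(n)]

    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    ii, jj = np.nonzero((d < distance_threshold) & ~np.eye(n, dtype=bool))
    for i, j in zip(ii, jj):
        neighbors[i].add(int(j))

    if use_triangulation:
        if n < 3:
            raise LayoutError("triangulation requires at least 3 electrodes")
        from scipy.spatial import Delaunay, QhullError

        pts = _azimuthal_equidistant(pos)
        try:
            tri = Delaunay(pts)
        except QhullError as exc:
            raise LayoutError("electrode positions are degenerate (collinear)") from exc
        for simplex in tri.simplices:
            for a in range(3):
                i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                neighbors[i].add(j)
                neighbors[j].add(i)
    return AdjacencyStructure(neighbors=neighbors)
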