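"""Daura (GROMOS-style) RMSD clustering and bound/free cross-matching.

The Daura algorithm counts, for every unassigned frame, its neighbours
within an RMSD cutoff; the frame with most neighbours seeds a cluster
containing itself and those neighbours, the members are removed, and the
procedure repeats.  Ties on neighbour count are broken toward the lowest
frame index so cluster identity is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conformation import rmsd
from .synthetic import Ensemble

__all__ = [
    "Cluster", "ClusterSet", "CrossStateMatrix",
    "pairwise_rmsd_matrix", "daura_cluster", "top_k", "cross_state_matrix",
    "column_minima",
]


@dataclass
class Cluster:
    population: float          # percent of ALL frames
    members: np.ndarray        # frame indices (original numbering)
    representative: int        # frame index of the cluster centre
    representative_coords: np.ndarray | None = None


@dataclass
class ClusterSet:
    """Clusters ordered by population (percentages are global, sum to 100)."""

    clusters: list[Cluster]
    cutoff: float
    selection: np.ndarray | None = None
    n_frames: int = 0

    def __post_init__(self):
        if self.clusters:
            pops = [c.population for c in self.clusters]
            if abs(sum(pops) - 100.0) > 1e-6:
                raise ValueError("cluster populations must sum to 100%")
            if any(pops[i] < pops[i + 1] - 1e-12
                   for i in range(len(pops) - 1)):
                raise ValueError("clusters must be ordered by population")

    @property
    def populations(self) -> list[float]:
        return [c.population for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)


def pairwise_rmsd_matrix(coords: np.ndarray, superpose: bool = True,
                         chunk: int = 512) -> np.ndarray:
    """Symmetric frame-by-frame RMSD matrix (superposed by default).

    ``coords`` has shape (n_frames, n_points, 3).  Memory is O(N²) floats;
    the computation streams in chunks so only the matrix itself is held.
    """
    coords = np.asarray(coords, dtype=float)
    n, m, _ = coords.shape
    out = np.zeros((n, n))
    if not superpose:
        for i0 in range(0, n, chunk):
            block = coords[i0:i0 + chunk]
            diff = block[:, None] - coords[None]
            out[i0:i0 + chunk] = np.sqrt(
                (diff ** 2).sum(axis=-1).mean(axis=-1))
        return out
    centred = coords - coords.mean(axis=1, keepdims=True)
    sq = (centred ** 2).sum(axis=(1, 2))
    for i in range(n):
        # Kabsch RMSD via SVD of the cross-covariance, vectorised over j
        H = np.einsum("ak,jal->jkl", centred[i], centred[i + 1:])
        U, S, Vt = np.linalg.svd(H)
        det = np.sign(np.linalg.det(np.einsum("jkl,jlm->jkm", U, Vt)))
        S[:, -1] *= det
        msd = (sq[i] + sq[i + 1:] - 2.0 * S.sum(axis=1)) / m
        out[i, i + 1:] = out[i + 1:, i] = np.sqrt(np.maximum(msd, 0.0))
    return out


def daura_cluster(e: "Ensemble | np.ndarray", selection=None,
                  cutoff: float = 2.0, superpose: bool = True) -> ClusterSet:
    """Greedy neighbour-count clustering of an ensemble.

    ``e`` may be an Ensemble (with an optional atom ``selection``) or a raw
    (n_frames, n_points, 3) array.  RMSDs are computed after superposition.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if isinstance(e, Ensemble):
        coords = e.frames if selection is None else e.frames[:, selection]
    else:
        coords = np.asarray(e, dtype=float)
    n = len(coords)
    if n == 0:
        raise ValueError("empty ensemble")

    dmat = pairwise_rmsd_matrix(coords, superpose=superpose)
    adj = dmat <= cutoff
    unassigned = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while unassigned.any():
        counts = (adj & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centre = int(np.argmax(counts))  # argmax → lowest index on ties
        members = np.where(adj[centre] & unassigned)[0]
        clusters.append(Cluster(
            population=100.0 * len(members) / n,
            members=members, representative=centre,
            representative_coords=coords[centre].copy()))
        unassigned[members] = False
    clusters.sort(key=lambda c: (-c.population, c.representative))
    sel = None if selection is None else np.asarray(selection, dtype=int)
    return ClusterSet(clusters=clusters, cutoff=cutoff, selection=sel,
                      n_frames=n)


def top_k(cs: ClusterSet, k: int) -> ClusterSet:
    """First k clusters by population; global percentages are retained
    (not renormalised)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(cs.clusters):
        warnings.warn(f"requested top {k} clusters but only "
                      f"{len(cs.clusters)} exist; returning all")
        k = len(cs.clusters)
    out = ClusterSet.__new__(ClusterSet)
    out.clusters = cs.clusters[:k]
    out.cutoff = cs.cutoff
    out.selection = cs.selection
    out.n_frames = cs.n_frames
    return out


def column_minima(matrix: np.ndarray) -> list[tuple[int, float]]:
    """Per-column (row index, value) minima; exhaustive and deterministic
    (lowest row index on ties)."""
    matrix = np.asarray(matrix, dtype=float)
    return [(int(np.argmin(matrix[:, j])), float(matrix[:, j].min()))
            for j in range(matrix.shape[1])]


@dataclass
class CrossStateMatrix:
    """RMSD matrix between free-state (rows) and bound-state (columns)
    cluster representatives, with per-column and per-row minima flagged —
    the free cluster most similar to each bound cluster and vice versa."""

    rmsd_matrix: np.ndarray
    row_populations: list[float] = field(default_factory=list)
    col_populations: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.rmsd_matrix = np.asarray(self.rmsd_matrix, dtype=float)

    @property
    def col_minima(self) -> list[tuple[int, float]]:
        return column_minima(self.rmsd_matrix)

    @property
    def row_minima(self) -> list[tuple[int, float]]:
        return [(j, v) for j, v in column_minima(self.rmsd_matrix.T)]

    @property
    def global_min(self) -> float:
        return float(self.rmsd_matrix.min())

    def min_flags(self, per: str = "column") -> np.ndarray:
        """Boolean mask of the flagged minima cells."""
        flags = np.zeros(self.rmsd_matrix.shape, dtype=bool)
        if per == "column":
            for j, (i, _) in enumerate(self.col_minima):
                flags[i, j] = True
        elif per == "row":
            for i, (j, _) in enumerate(self.row_minima):
                flags[i, j] = True
        else:
            raise ValueError("per must be 'column' or 'row'")
        return flags


def cross_state_matrix(free: ClusterSet, bound: ClusterSet) -> CrossStateMatrix:
    """Superposed RMSD between every free and bound cluster representative."""
    if free.selection is not None and bound.selection is not None:
        if (len(free.selection) != len(bound.selection)
                or np.any(free.selection != bound.selection)):
            raise ValueError("cluster sets use different atom selections")
    mat = np.empty((len(free.clusters), len(bound.clusters)))
    for i, cf in enumerate(free.clusters):
        for j, cb in enumerate(bound.clusters):
            if (cf.representative_coords is None
                    or cb.representative_coords is None):
                raise ValueError("cluster sets lack representative "
                                 "coordinates")
            mat[i, j] = rmsd(cf.representative_coords,
                             cb.representative_coords)
    return CrossStateMatrix(
        rmsd_matrix=mat,
        row_populations=free.populations,
        col_populations=bound.populations,
    )
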