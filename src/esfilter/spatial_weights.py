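"""Distance-kernel spatial weights and their double-centered form.

The weights matrix C0 has (i, j) entry exp(-d_ij / r) where d_ij is the
Euclidean distance between stations and r is the longest edge of the
minimum spanning tree over the station network.  C1 = M C0 M with
M = I - 11'/n is the doubly centered matrix whose eigenvectors provide
the candidate spatial filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .stations import StationSet

__all__ = [
    "SpatialWeights",
    "pairwise_distances",
    "mst_longest_edge",
    "exp_kernel_weights",
    "center_weights",
    "build_weights",
]

#: symmetry / centering tolerance, scaled by n where matrices are involved
CENTER_TOL = 1e-9


@dataclass
class SpatialWeights:
    """Kernel weights C0, kernel range r and the centered matrix C1."""

    C0: np.ndarray
    r: float
    C1: np.ndarray
    diagonal: float = 0.0

    @property
    def n(self) -> int:
        return self.C0.shape[0]

    def __post_init__(self) -> None:
        n = self.C0.shape[0]
        if self.C0.shape != (n, n) or self.C1.shape != (n, n):
            raise ValueError("C0 and C1 must be square and of equal shape")
        if self.r <= 0:
            raise ValueError(f"kernel range r must be positive, got {self.r}")
        if not np.allclose(self.C0, self.C0.T, atol=CENTER_TOL * n):
            raise ValueError("C0 must be symmetric")
        rowsums = self.C1.sum(axis=1)
        if np.max(np.abs(rowsums)) > CENTER_TOL * n:
            raise ValueError("C1 rows must sum to zero (not properly centered)")


def _coords(stations) -> np.ndarray:
    if isinstance(stations, StationSet):
        return stations.xy
    xy = np.asarray(stations, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("expected an (n, 2) coordinate array or a StationSet")
    return xy


def pairwise_distances(stations) -> np.ndarray:
    """Full Euclidean distance matrix between stations.

    Raises if two stations share a coordinate pair: a zero off-diagonal
    distance would break the strictly-decreasing kernel and the MST range.
    """
    xy = _coords(stations)
    D = squareform(pdist(xy))
    off = ~np.eye(len(xy), dtype=bool)
    if np.any(D[off] == 0.0):
        i, j = np.argwhere((D == 0.0) & off)[0]
        raise ValueError(f"stations {i} and {j} have identical coordinates")
    return D


def mst_longest_edge(D: np.ndarray) -> float:
    """Longest edge weight in a minimum spanning tree of the complete graph."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 stations for a spanning tree")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    tree = minimum_spanning_tree(csr_matrix(D))
    return float(tree.data.max())


def exp_kernel_weights(D: np.ndarray, r: float, diagonal: float = 0.0) -> np.ndarray:
    """Exponential distance-decay kernel exp(-d/r) with a fixed diagonal.

    The kernel itself gives exp(0) = 1 on the diagonal; by convention
    self-influence is excluded (diagonal 0) before centering.  The
    convention is configurable via ``diagonal``.
    """
    if r <= 0:
        raise ValueError(f"kernel range r must be positive, got {r}")
    C0 = np.exp(-np.asarray(D, dtype=float) / r)
    np.fill_diagonal(C0, diagonal)
    return C0


def center_weights(C0: np.ndarray) -> np.ndarray:
    """Double-center a weights matrix: C1 = (I - 11'/n) C0 (I - 11'/n)."""
    C0 = np.asarray(C0, dtype=float)
    if C0.ndim != 2 or C0.shape[0] != C0.shape[1]:
        raise ValueError(f"C0 must be square, got shape {C0.shape}")
    # M C0 M expanded: subtract row means, column means, add grand mean
    row_mean = C0.mean(axis=1, keepdims=True)
    col_mean = C0.mean(axis=0, keepdims=True)
    grand = C0.mean()
    return C0 - row_mean - col_mean + grand


def build_weights(stations, diagonal: float = 0.0) -> SpatialWeights:
    """Distances -> MST range -> kernel -> centering, in one call."""
    D = pairwise_distances(stations)
    r = mst_longest_edge(D)
    C0 = exp_kernel_weights(D, r, diagonal=diagonal)
    C1 = center_weights(C0)
    return SpatialWeights(C0=C0, r=r, C1=C1, diagonal=diagonal)
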