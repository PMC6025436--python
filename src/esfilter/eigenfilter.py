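"""Eigendecomposition of the centered weights and candidate selection.

Eigenvectors of C1 ordered by descending eigenvalue are the pool of
synthetic spatial covariates; the candidate subset keeps the vectors with
eigenvalue ratio lambda_j / lambda_1 >= threshold (default 0.10), i.e. the
strongly positively autocorrelated patterns.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EigenBasis",
    "CandidateSet",
    "eigendecompose",
    "select_candidates",
    "moran_coefficient_of_vector",
]

SYM_TOL = 1e-8


@dataclass
class EigenBasis:
    """Full spectral decomposition of C1, descending, sign-normalized."""

    eigenvalues: np.ndarray  # length n, descending
    eigenvectors: np.ndarray  # n x n, column j pairs with eigenvalues[j]
    source_hash: str = ""

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    def vector(self, j: int) -> np.ndarray:
        return self.eigenvectors[:, j]


@dataclass
class CandidateSet:
    indices: list[int] = field(default_factory=list)
    threshold: float = 0.10

    def __len__(self) -> int:
        return len(self.indices)


def eigendecompose(C1: np.ndarray, tol: float = SYM_TOL) -> EigenBasis:
    """Real spectral decomposition of a symmetric centered weights matrix.

    Eigenvalues are sorted descending; each eigenvector is normalized so
    that its entry of largest magnitude is positive (first such entry on
    ties), making signs — and hence downstream coefficients and maps —
    reproducible across LAPACK builds.
    """
    C1 = np.asarray(C1, dtype=float)
    scale = max(1.0, np.abs(C1).max())
    if np.max(np.abs(C1 - C1.T)) > tol * scale:
        raise ValueError("input matrix is not symmetric within tolerance")
    w, v = np.linalg.eigh((C1 + C1.T) / 2.0)
    order = np.argsort(-w, kind="stable")
    w = w[order]
    v = v[:, order]
    # sign convention: largest-magnitude entry positive
    lead = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[lead, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    v = v * signs
    digest = hashlib.sha256(np.ascontiguousarray(C1).tobytes()).hexdigest()[:16]
    return EigenBasis(eigenvalues=w, eigenvectors=v, source_hash=digest)


def select_candidates(basis: EigenBasis, threshold: float = 0.10) -> CandidateSet:
    """Indices j with lambda_j / lambda_1 >= threshold, boundary inclusive."""
    lam = basis.eigenvalues
    if lam[0] <= 0:
        raise ValueError(
            "no positive-autocorrelation eigenvectors (largest eigenvalue <= 0)"
        )
    idx = [int(j) for j in range(len(lam)) if lam[j] / lam[0] >= threshold]
    return CandidateSet(indices=idx, threshold=threshold)


def moran_coefficient_of_vector(v: np.ndarray, C0: np.ndarray) -> float:
    """Moran coefficient MC(v) = (n / S0) * (v' C1 v) / (v' M v).

    For eigenvector j of C1 this equals (n / S0) * lambda_j exactly,
    which ties the eigenvalue ordering to spatial autocorrelation strength.
    """
    v = np.asarray(v, dtype=float)
    C0 = np.asarray(C0, dtype=float)
    n = len(v)
    z = v - v.mean()
    denom = z @ z
    if denom <= 1e-15 * max(1.0, v @ v):
        raise ValueError("vector is constant; Moran coefficient undefined")
    S0 = C0.sum()
    # v' C1 v == z' C0 z since centering annihilates the mean component
    return float(n / S0 * (z @ C0 @ z) / denom)
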