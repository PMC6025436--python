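"""Independent reference implementations used to cross-check the package.

Everything here is deliberately brute-force (double loops, exhaustive
enumeration, dense solves) and shares no code with the library paths it
verifies.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import statsmodels.api as sm


def distances_bruteforce(xy: np.ndarray) -> np.ndarray:
    n = len(xy)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt((xy[i, 0] - xy[j, 0]) ** 2 + (xy[i, 1] - xy[j, 1]) ** 2)
    return D


def _is_spanning_tree(n: int, edges) -> bool:
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri == rj:
            return False
        parent[ri] = rj
    return True


def mst_max_edge_exhaustive(D: np.ndarray) -> float:
    """Max edge of the minimum-total-weight spanning tree, by enumeration."""
    n = D.shape[0]
    all_edges = list(itertools.combinations(range(n), 2))
    best_total, best_max = np.inf, None
    for subset in itertools.combinations(all_edges, n - 1):
        if not _is_spanning_tree(n, subset):
            continue
        total = sum(D[i, j] for i, j in subset)
        if total < best_total:
            best_total = total
            best_max = max(D[i, j] for i, j in subset)
    return best_max


def moran_double_sum(x: np.ndarray, W: np.ndarray) -> float:
    n = len(x)
    xbar = x.mean()
    num = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * (x[i] - xbar) * (x[j] - xbar)
    den = sum((xi - xbar) ** 2 for xi in x)
    return n / W.sum() * num / den


def moran_randomization_variance(x: np.ndarray, W: np.ndarray) -> float:
    """Cliff-Ord randomization variance, coded independently with loops."""
    n = len(x)
    S0 = W.sum()
    S1 = 0.0
    for i in range(n):
        for j in range(n):
            S1 += (W[i, j] + W[j, i]) ** 2
    S1 /= 2.0
    S2 = 0.0
    for i in range(n):
        S2 += (W[i, :].sum() + W[:, i].sum()) ** 2
    z = x - x.mean()
    b2 = n * (z**4).sum() / (z**2).sum() ** 2
    EI = -1.0 / (n - 1)
    A = n * ((n * n - 3 * n + 3) * S1 - n * S2 + 3 * S0 * S0)
    B = b2 * ((n * n - n) * S1 - 2 * n * S2 + 6 * S0 * S0)
    return (A - B) / ((n - 1) * (n - 2) * (n - 3) * S0 * S0) - EI * EI


def naive_stepwise(y, covariates: pd.DataFrame, cand_indices, basis) -> list[int]:
    """Greedy forward selection by refitting every candidate model."""
    zy = (y - y.mean()) / y.std(ddof=1)
    Z = covariates.apply(lambda c: (c - c.mean()) / c.std(ddof=1)).to_numpy()
    selected: list[int] = []
    remaining = list(cand_indices)

    def adj(indices):
        cols = [np.ones(len(y)), Z] + [basis.eigenvectors[:, [j]] for j in indices]
        X = np.column_stack(cols)
        return sm.OLS(zy, X).fit().rsquared_adj

    current = adj(selected)
    while remaining:
        scores = [(adj(selected + [j]), j) for j in remaining]
        best_score, best_j = max(scores)
        if best_score <= current:
            break
        current = best_score
        selected.append(best_j)
        remaining.remove(best_j)
    return selected


def kriging_dense_solve(xy, values, gamma, target):
    """Augmented ordinary-kriging system solved directly with numpy."""
    k = len(xy)
    A = np.zeros((k + 1, k + 1))
    for i in range(k):
        for j in range(k):
            A[i, j] = gamma(np.linalg.norm(xy[i] - xy[j]))
        A[i, k] = A[k, i] = 1.0
    b = np.zeros(k + 1)
    for i in range(k):
        b[i] = gamma(np.linalg.norm(target - xy[i]))
    b[k] = 1.0
    sol = np.linalg.solve(A, b)
    return float(sol[:k] @ values), sol[:k]


def line_length_in_disk_sampled(p0, p1, center, radius, n_samples=20_000):
    """Numeric integration of the in-disk indicator along a segment."""
    t = (np.arange(n_samples) + 0.5) / n_samples
    pts = p0[None, :] + t[:, None] * (p1 - p0)[None, :]
    inside = np.linalg.norm(pts - center[None, :], axis=1) <= radius
    return inside.mean() * np.linalg.norm(p1 - p0)


def nystrom_explicit_matrices(basis, C0, krow, indices):
    """Extension via explicit centering matrices: c~ = M (c - C0 1 / n)."""
    n = C0.shape[0]
    M = np.eye(n) - np.ones((n, n)) / n
    ctil = M @ (krow - C0 @ np.ones(n) / n)
    out = []
    for j in indices:
        out.append(ctil @ basis.eigenvectors[:, j] / basis.eigenvalues[j])
    return np.array(out)
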