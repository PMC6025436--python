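"""Leave-one-out cross-validation with out-of-sample eigenvector extension.

Each fold rebuilds the spatial weights (distances, MST range, kernel,
centering), re-runs eigenvector selection and model fitting on the n - 1
training stations, extends the selected eigenvectors to the held-out
location via the Nystrom projection of the centered kernel, and predicts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .eigenfilter import EigenBasis, eigendecompose, select_candidates
from .regression import (
    CollinearityError,
    ESFRModel,
    fit_ols,
    forward_stepwise_eigen,
    prune_and_refit,
)
from .spatial_weights import build_weights, exp_kernel_weights
from .stations import StationSet

__all__ = ["CVResult", "CVSpec", "nystrom_extend", "kernel_row", "loocv"]


@dataclass
class CVSpec:
    """Model configuration applied identically in every fold."""

    use_filter: bool = True  # False -> GMLR baseline
    threshold: float = 0.10
    alpha_level: float = 0.10
    diagonal: float = 0.0
    prune: bool = False  # per-fold covariate pruning (off: selection + OLS only)


@dataclass
class CVResult:
    per_station: pd.DataFrame  # station_id, observed, predicted, flagged
    mse: float
    rmse: float
    n_folds: int
    n_failed: int = 0

    def to_summary(self) -> dict:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "n_folds": self.n_folds,
            "n_failed": self.n_failed,
        }


def kernel_row(
    xy0: np.ndarray, train_xy: np.ndarray, r: float, diagonal: float = 0.0
) -> np.ndarray:
    """Kernel weights exp(-d(s0, s_i)/r) from a new location to the stations.

    Zero distances (s0 coincides with a training station) receive the
    diagonal convention value so the in-sample Nystrom identity holds.
    """
    d = np.linalg.norm(np.asarray(train_xy, dtype=float) - np.asarray(xy0, dtype=float), axis=1)
    row = np.exp(-d / r)
    row[d == 0.0] = diagonal
    return row


def nystrom_extend(
    basis: EigenBasis,
    C0: np.ndarray,
    kernel_row: np.ndarray,
    indices: Sequence[int],
) -> np.ndarray:
    """Eigenvector values at an unobserved location.

    The kernel row c is double-centered against the training kernel,
    c~_i = c_i - mean(c) - colmean_i(C0) + grandmean(C0), and projected:
    e~_j(s0) = c~' e_j / lambda_j.  Undefined for non-positive eigenvalues.
    """
    indices = list(indices)
    lam = basis.eigenvalues[indices]
    if np.any(lam <= 0):
        bad = [j for j, l in zip(indices, lam) if l <= 0]
        raise ValueError(f"Nystrom extension undefined for non-positive eigenvalues: {bad}")
    c = np.asarray(kernel_row, dtype=float)
    C0 = np.asarray(C0, dtype=float)
    ctil = c - c.mean() - C0.mean(axis=0) + C0.mean()
    return (ctil @ basis.eigenvectors[:, indices]) / lam


def extend_to_points(
    basis: EigenBasis,
    C0: np.ndarray,
    train_xy: np.ndarray,
    r: float,
    points_xy: np.ndarray,
    indices: Sequence[int],
    diagonal: float = 0.0,
) -> np.ndarray:
    """Vectorized Nystrom extension at many locations: (m, k) matrix."""
    indices = list(indices)
    lam = basis.eigenvalues[indices]
    if np.any(lam <= 0):
        bad = [j for j, l in zip(indices, lam) if l <= 0]
        raise ValueError(f"Nystrom extension undefined for non-positive eigenvalues: {bad}")
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    d = np.linalg.norm(pts[:, None, :] - np.asarray(train_xy)[None, :, :], axis=2)
    rows = np.exp(-d / r)
    rows[d == 0.0] = diagonal
    C0 = np.asarray(C0, dtype=float)
    ctil = rows - rows.mean(axis=1, keepdims=True) - C0.mean(axis=0)[None, :] + C0.mean()
    return (ctil @ basis.eigenvectors[:, indices]) / lam


def _fit_fold(train: StationSet, spec: CVSpec):
    weights = build_weights(train, diagonal=spec.diagonal)
    if not spec.use_filter:
        return weights, None, fit_ols(train.values, train.covariates)
    basis = eigendecompose(weights.C1)
    candidates = select_candidates(basis, threshold=spec.threshold)
    eigen = forward_stepwise_eigen(train.values, train.covariates, candidates, basis)
    model = fit_ols(train.values, train.covariates, basis=basis, eigen_indices=eigen)
    if spec.prune:
        model = prune_and_refit(
            model, train.values, train.covariates, basis, candidates, spec.alpha_level
        )
    return weights, basis, model


def _predict_held_out(
    model: ESFRModel,
    basis: EigenBasis | None,
    weights,
    train: StationSet,
    xy0: np.ndarray,
    covariates_row: pd.DataFrame,
    diagonal: float,
) -> float:
    eigen_vals = None
    if model.is_spatial:
        row = kernel_row(xy0, train.xy, weights.r, diagonal=diagonal)
        eigen_vals = nystrom_extend(basis, weights.C0, row, model.eigen_indices)[None, :]
    return float(model.predict(covariates_row, eigen_vals)[0])


def loocv(stations: StationSet, spec: CVSpec | None = None) -> CVResult:
    """Leave-one-out cross-validation of the configured model.

    Folds with a rank-deficient training design are flagged and excluded
    from the error summary rather than aborting the whole validation.
    """
    spec = spec or CVSpec()
    n = len(stations)
    if n < 10:
        raise ValueError(f"LOOCV needs at least 10 stations, got {n}")
    preds = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)
    all_idx = np.arange(n)
    for i in range(n):
        train = stations.subset(all_idx != i)
        try:
            weights, basis, model = _fit_fold(train, spec)
            preds[i] = _predict_held_out(
                model,
                basis,
                weights,
                train,
                stations.xy[i],
                stations.covariates.iloc[[i]],
                spec.diagonal,
            )
        except CollinearityError:
            flagged[i] = True
    ok = ~flagged
    err = stations.values[ok] - preds[ok]
    mse = float(np.mean(err**2))
    per_station = pd.DataFrame(
        {
            "station_id": stations.ids,
            "observed": stations.values,
            "predicted": preds,
            "flagged": flagged,
        }
    )
    return CVResult(
        per_station=per_station,
        mse=mse,
        rmse=float(np.sqrt(mse)),
        n_folds=n,
        n_failed=int(flagged.sum()),
    )
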