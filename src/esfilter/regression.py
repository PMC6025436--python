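"""Spatially filtered regression: stepwise eigenvector selection and OLS.

The model is y = X beta + E alpha + eps where X holds z-scored covariates
and E holds selected eigenvectors of the centered spatial weights matrix.
The non-spatial baseline (no E columns) is the GMLR model.  Response and
covariates are z-scored before fitting, so reported coefficients are on
the standardized (Beta) scale; error metrics are reported on the raw
response scale using the stored standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg

from ._util import round_half_up
from .eigenfilter import CandidateSet, EigenBasis

__all__ = [
    "FitReport",
    "ESFRModel",
    "CollinearityError",
    "fit_ols",
    "fit_gmlr",
    "forward_stepwise_eigen",
    "prune_and_refit",
    "percent_change",
]

_RANK_TOL = 1e-10


class CollinearityError(ValueError):
    """Raised for rank-deficient designs; carries the offending columns."""

    def __init__(self, columns: Sequence[str]):
        self.columns = list(columns)
        super().__init__(f"design is rank deficient; collinear columns: {self.columns}")


@dataclass
class FitReport:
    """Goodness-of-fit metrics on the raw response scale."""

    r2_adj: float
    rse: float
    mape: float | None  # None when some observed value is exactly 0
    aicc: float
    n: int
    p: int  # fitted parameters excluding the intercept


@dataclass
class ESFRModel:
    covariate_names: list[str]
    eigen_indices: list[int]
    beta: np.ndarray  # standardized-scale covariate coefficients
    alpha: np.ndarray  # eigenvector coefficients (standardized-response scale)
    intercept: float
    residuals: np.ndarray  # raw response scale
    fitted: np.ndarray  # raw response scale
    fit: FitReport
    standardization: dict[str, tuple[float, float]]  # name -> (mean, sd); response key "__response__"
    pvalues: dict[str, float] = field(default_factory=dict)
    alpha_pvalues: dict[int, float] = field(default_factory=dict)
    pruned: list[str] = field(default_factory=list)

    @property
    def is_spatial(self) -> bool:
        return len(self.eigen_indices) > 0

    def predict(
        self, covariates: pd.DataFrame, eigen_values: np.ndarray | None = None
    ) -> np.ndarray:
        """Predict raw-scale response for new rows.

        ``eigen_values`` must provide one column per selected eigenvector,
        evaluated at the new locations (e.g. via Nystrom extension).
        """
        zpred = np.full(len(covariates), self.intercept, dtype=float)
        for name, b in zip(self.covariate_names, self.beta):
            mu, sd = self.standardization[name]
            zpred += b * (covariates[name].to_numpy(dtype=float) - mu) / sd
        zpred += self.filter_component(eigen_values)
        mu_y, sd_y = self.standardization["__response__"]
        return mu_y + sd_y * zpred

    def filter_component(self, eigen_values: np.ndarray | None) -> np.ndarray:
        """Spatial-filter contribution (standardized-response scale)."""
        if not self.eigen_indices:
            return 0.0 if eigen_values is None else np.zeros(len(eigen_values))
        if eigen_values is None:
            raise ValueError("model has eigenvectors; eigen_values required")
        E = np.asarray(eigen_values, dtype=float)
        if E.ndim == 1:
            E = E[:, None]
        if E.shape[1] != len(self.eigen_indices):
            raise ValueError(
                f"expected {len(self.eigen_indices)} eigenvector columns, got {E.shape[1]}"
            )
        return E @ self.alpha

    def to_dict(self) -> dict:
        """JSON-ready summary; pruned covariates carry beta null ('/' marker)."""
        cov = [
            {"name": n, "beta": float(b), "p": float(self.pvalues[n])}
            for n, b in zip(self.covariate_names, self.beta)
        ]
        cov += [{"name": n, "beta": None, "p": None} for n in self.pruned]
        return {
            "covariates": cov,
            "eigen": [
                {"index": int(j), "alpha": float(a)}
                for j, a in zip(self.eigen_indices, self.alpha)
            ],
            "intercept": float(self.intercept),
            "fit": {
                "r2_adj": self.fit.r2_adj,
                "rse": self.fit.rse,
                "mape": self.fit.mape,
                "aicc": self.fit.aicc,
                "n": self.fit.n,
                "p": self.fit.p,
            },
            "standardization": {
                k: [float(m), float(s)] for k, (m, s) in self.standardization.items()
            },
        }


def _zscore_columns(covariates: pd.DataFrame) -> tuple[np.ndarray, dict]:
    std = {}
    cols = []
    for name in covariates.columns:
        x = covariates[name].to_numpy(dtype=float)
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0.0:
            raise ValueError(f"covariate {name!r} is constant; cannot standardize")
        std[name] = (mu, sd)
        cols.append((x - mu) / sd)
    Z = np.column_stack(cols) if cols else np.empty((len(covariates), 0))
    return Z, std


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[1] == 0:
        return
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(R))
    tol = d.max() * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    bad = [names[piv[k]] for k in range(len(d)) if d[k] <= tol]
    if bad:
        raise CollinearityError(bad)


def _eigen_matrix(basis: EigenBasis, indices: Sequence[int]) -> np.ndarray:
    return basis.eigenvectors[:, list(indices)]


def fit_ols(
    y: np.ndarray,
    design: pd.DataFrame,
    basis: EigenBasis | None = None,
    eigen_indices: Sequence[int] = (),
) -> ESFRModel:
    """OLS on the standardized design; metrics on the raw response scale.

    r2_adj = 1 - (1 - R^2)(n - 1)/(n - p - 1); rse = sqrt(RSS/(n - p - 1));
    mape = (100/n) sum |e_i| / y_i (undefined if any y_i = 0);
    aicc = aic + 2k(k + 1)/(n - k - 1) with Gaussian ML likelihood and
    k = p + 2 (intercept + error variance).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    eigen_indices = list(eigen_indices)
    if eigen_indices and basis is None:
        raise ValueError("eigen_indices given without a basis")
    Z, std = _zscore_columns(design)
    E = _eigen_matrix(basis, eigen_indices) if eigen_indices else np.empty((n, 0))
    p = Z.shape[1] + E.shape[1]
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 observations (n={n}, p={p})")
    mu_y, sd_y = float(y.mean()), float(y.std(ddof=1))
    if sd_y == 0.0:
        raise ValueError("response is constant")
    std["__response__"] = (mu_y, sd_y)
    zy = (y - mu_y) / sd_y

    names = ["const"] + list(design.columns) + [f"E{j}" for j in eigen_indices]
    X = np.column_stack([np.ones(n), Z, E])
    _check_rank(X, names)

    res = sm.OLS(zy, X).fit()
    k_cov = Z.shape[1]
    beta = res.params[1 : 1 + k_cov]
    alpha = res.params[1 + k_cov :]
    resid = sd_y * res.resid
    fitted = y - resid
    rss = float(resid @ resid)
    rse = float(np.sqrt(rss / (n - p - 1)))
    if np.any(y == 0.0):
        mape: float | None = None
    else:
        mape = float(100.0 / n * np.sum(np.abs(resid) / y))
    k = p + 2
    ll = -n / 2.0 * (np.log(2.0 * np.pi * rss / n) + 1.0)
    aic = -2.0 * ll + 2.0 * k
    aicc = aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)
    report = FitReport(
        r2_adj=float(res.rsquared_adj), rse=rse, mape=mape, aicc=float(aicc), n=n, p=p
    )
    return ESFRModel(
        covariate_names=list(design.columns),
        eigen_indices=eigen_indices,
        beta=np.asarray(beta, dtype=float),
        alpha=np.asarray(alpha, dtype=float),
        intercept=float(res.params[0]),
        residuals=resid,
        fitted=fitted,
        fit=report,
        standardization=std,
        pvalues={nm: float(pv) for nm, pv in zip(design.columns, res.pvalues[1 : 1 + k_cov])},
        alpha_pvalues={
            int(j): float(pv) for j, pv in zip(eigen_indices, res.pvalues[1 + k_cov :])
        },
    )


def fit_gmlr(y: np.ndarray, covariates: pd.DataFrame) -> ESFRModel:
    """Non-spatial baseline: plain OLS on the covariates alone."""
    return fit_ols(y, covariates)


def forward_stepwise_eigen(
    y: np.ndarray,
    covariates: pd.DataFrame,
    candidates: CandidateSet,
    basis: EigenBasis,
) -> list[int]:
    """Greedy forward selection of eigenvectors with covariates forced in.

    At each round the candidate that maximizes adjusted R^2 is added; the
    search stops when no addition increases adjusted R^2.  Implemented by
    incremental orthogonalization so each round costs O(n * n_candidates)
    instead of refitting every candidate model from scratch.
    """
    if not candidates.indices:
        raise ValueError("candidate set is empty")
    y = np.asarray(y, dtype=float)
    n = len(y)
    mu_y, sd_y = y.mean(), y.std(ddof=1)
    if sd_y == 0.0:
        raise ValueError("response is constant")
    zy = (y - mu_y) / sd_y
    Z, _ = _zscore_columns(covariates)
    X0 = np.column_stack([np.ones(n), Z])
    _check_rank(X0, ["const"] + list(covariates.columns))
    Q, _ = np.linalg.qr(X0)

    cand = list(candidates.indices)
    U = basis.eigenvectors[:, cand].copy()
    U -= Q @ (Q.T @ U)
    resid = zy - Q @ (Q.T @ zy)
    rss = float(resid @ resid)
    tss = float(zy @ zy)  # z-scored response: (n - 1) up to rounding
    p = Z.shape[1]

    def adj_r2(rss_val: float, p_val: int) -> float:
        dof = n - p_val - 1
        if dof <= 0:
            return -np.inf
        return 1.0 - (rss_val / dof) / (tss / (n - 1))

    selected: list[int] = []
    active = np.arange(len(cand))
    current = adj_r2(rss, p)
    while active.size and n - (p + len(selected) + 1) - 1 > 1:
        nu2 = np.einsum("ij,ij->j", U[:, active], U[:, active])
        usable = nu2 > _RANK_TOL * n
        if not usable.any():
            break
        proj = U[:, active].T @ zy
        gains = np.where(usable, proj**2 / np.where(usable, nu2, 1.0), -np.inf)
        new_p = p + len(selected) + 1
        adj_new = adj_r2(rss - gains.max(), new_p)
        if adj_new <= current:
            break
        best = int(np.argmax(gains))
        col = active[best]
        q = U[:, col] / np.sqrt(nu2[best])
        rss -= float(gains[best])
        current = adj_new
        selected.append(cand[col])
        active = np.delete(active, best)
        if active.size:
            U[:, active] -= np.outer(q, q @ U[:, active])
    return selected


def prune_and_refit(
    model: ESFRModel,
    y: np.ndarray,
    covariates: pd.DataFrame,
    basis: EigenBasis,
    candidates: CandidateSet,
    alpha_level: float = 0.10,
) -> ESFRModel:
    """Drop covariates with p > alpha_level, then redo selection and OLS once.

    If nothing is pruned the fitted model is returned unchanged (re-running
    the selection on an identical covariate set is a fixed point).  If all
    covariates are pruned, an eigenvectors-only model is fitted with a
    warning.
    """
    drop = [nm for nm in model.covariate_names if model.pvalues[nm] > alpha_level]
    if not drop:
        return model
    keep = [nm for nm in model.covariate_names if nm not in drop]
    reduced = covariates[keep]
    if not keep:
        warnings.warn(
            "all covariates pruned; refitting with eigenvectors only", stacklevel=2
        )
    if model.is_spatial or len(candidates) > 0:
        eigen = forward_stepwise_eigen(y, reduced, candidates, basis)
    else:
        eigen = []
    refit = fit_ols(y, reduced, basis=basis, eigen_indices=eigen)
    refit.pruned = list(model.pruned) + drop
    return refit


def percent_change(reference: float, comparison: float, mode: str = "increase") -> float:
    """Report-table comparison arithmetic, rounded half-up to one decimal.

    increase: 100 (comparison - reference) / reference;
    decrease: 100 (reference - comparison) / reference.
    """
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    if mode == "increase":
        pct = 100.0 * (comparison - reference) / reference
    elif mode == "decrease":
        pct = 100.0 * (reference - comparison) / reference
    else:
        raise ValueError(f"mode must be 'increase' or 'decrease', got {mode!r}")
    return round_half_up(pct, 1)
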