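"""Global Moran's I with significance, and Pearson correlation screening.

Moran's I uses the exponential-kernel weights (zero diagonal,
unstandardized) so the autocorrelation diagnostics and the eigenvector
basis share one spatial structure; row-standardized weights are available
behind a flag.  The p-value is the analytic normal approximation under
the randomization assumption, one-sided for positive autocorrelation
(so strongly negative I yields p near 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regression import ESFRModel
from .stations import StationSet

__all__ = ["MoranResult", "global_moran", "residual_moran", "pearson_table"]


@dataclass
class MoranResult:
    I: float
    expected: float
    variance: float
    z: float
    p: float  # one-sided upper tail (alternative: positive autocorrelation)


def _row_standardize(W: np.ndarray) -> np.ndarray:
    rs = W.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return W / rs


def global_moran(
    values: np.ndarray, C0: np.ndarray, row_standardize: bool = False
) -> MoranResult:
    """Global Moran's I with randomization-assumption moments.

    I = (n / S0) sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2.
    """
    x = np.asarray(values, dtype=float)
    W = np.asarray(C0, dtype=float)
    n = len(x)
    if row_standardize:
        W = _row_standardize(W)
    z = x - x.mean()
    m2 = z @ z
    if m2 <= 1e-15 * max(1.0, x @ x):
        raise ValueError("values are constant; Moran's I undefined")
    S0 = W.sum()
    I = float(n / S0 * (z @ W @ z) / m2)

    expected = -1.0 / (n - 1)
    # Cliff-Ord randomization variance
    S1 = 0.5 * np.sum((W + W.T) ** 2)
    S2 = np.sum((W.sum(axis=1) + W.sum(axis=0)) ** 2)
    b2 = n * np.sum(z**4) / m2**2
    num = n * ((n**2 - 3 * n + 3) * S1 - n * S2 + 3 * S0**2) - b2 * (
        (n**2 - n) * S1 - 2 * n * S2 + 6 * S0**2
    )
    variance = num / ((n - 1) * (n - 2) * (n - 3) * S0**2) - expected**2
    zscore = (I - expected) / np.sqrt(variance)
    p = float(stats.norm.sf(zscore))
    return MoranResult(I=I, expected=expected, variance=float(variance), z=float(zscore), p=p)


def residual_moran(
    model: ESFRModel, C0: np.ndarray, row_standardize: bool = False
) -> MoranResult:
    """Moran's I of the model residuals: the filtered-out-autocorrelation check."""
    return global_moran(model.residuals, C0, row_standardize=row_standardize)


def pearson_table(
    stations: StationSet, two_sided_levels: tuple[float, float] = (0.05, 0.01)
) -> pd.DataFrame:
    """Pearson correlation of each covariate with the response.

    Returns columns (covariate, pcc, p, marker) with '' / '*' / '**'
    significance markers at the two two-sided levels; a zero-variance
    covariate yields NaN pcc and an empty marker.
    """
    lo, hi = max(two_sided_levels), min(two_sided_levels)
    rows = []
    y = stations.values
    for name in stations.covariate_names:
        x = stations.covariates[name].to_numpy(dtype=float)
        if np.std(x) == 0.0:
            rows.append((name, np.nan, np.nan, ""))
            continue
        pcc, p = stats.pearsonr(x, y)
        marker = "**" if p < hi else "*" if p < lo else ""
        rows.append((name, float(pcc), float(p), marker))
    return pd.DataFrame(rows, columns=["covariate", "pcc", "p", "marker"])
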