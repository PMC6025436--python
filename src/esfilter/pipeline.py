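"""End-to-end estimation: weights -> eigenbasis -> selection -> OLS -> prune."""

from __future__ import annotations

from dataclasses import dataclass

from .eigenfilter import CandidateSet, EigenBasis, eigendecompose, select_candidates
from .regression import ESFRModel, fit_gmlr, fit_ols, forward_stepwise_eigen, prune_and_refit
from .spatial_weights import SpatialWeights, build_weights
from .stations import StationSet

__all__ = ["PipelineFit", "fit_pipeline"]


@dataclass
class PipelineFit:
    weights: SpatialWeights
    basis: EigenBasis
    candidates: CandidateSet
    esfr: ESFRModel
    gmlr: ESFRModel


def fit_pipeline(
    stations: StationSet,
    threshold: float = 0.10,
    alpha_level: float = 0.10,
    diagonal: float = 0.0,
    prune: bool = True,
) -> PipelineFit:
    """Run the five estimation steps and fit the non-spatial baseline.

    (1) spatial weights, (2) eigenvectors of the centered weights,
    (3) stepwise eigenvector selection with all covariates forced in,
    (4) OLS estimation, (5) pruning of insignificant covariates followed
    by one repetition of steps (3)-(4).
    """
    y = stations.values
    X = stations.covariates
    weights = build_weights(stations, diagonal=diagonal)
    basis = eigendecompose(weights.C1)
    candidates = select_candidates(basis, threshold=threshold)
    eigen = forward_stepwise_eigen(y, X, candidates, basis)
    esfr = fit_ols(y, X, basis=basis, eigen_indices=eigen)
    if prune:
        esfr = prune_and_refit(esfr, y, X, basis, candidates, alpha_level=alpha_level)
    gmlr = fit_gmlr(y, X)
    return PipelineFit(
        weights=weights, basis=basis, candidates=candidates, esfr=esfr, gmlr=gmlr
    )
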