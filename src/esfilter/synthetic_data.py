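"""Synthetic station networks, covariate fields, responses and geometries.

Everything is a pure function of (config, seed): independent random
streams are derived from one ``numpy.random.SeedSequence`` so that, e.g.,
generating or skipping the raster stack never changes the station draw.

The response is generated from the same model family the pipeline fits:
y = b0 + Z beta + sqrt(n - 1) E_k alpha + eps, with Z the z-scored
covariates and E_k true eigenvectors of the centered kernel, so the
eigenvector columns are scaled to unit sample variance and alpha is
directly comparable to beta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .eigenfilter import EigenBasis, CandidateSet, eigendecompose, select_candidates
from .gridding import RasterGrid
from .spatial_weights import SpatialWeights, build_weights
from .stations import StationSet

__all__ = [
    "CovariateSpec",
    "SimulationConfig",
    "SyntheticTruth",
    "gen_stations",
    "gen_covariate_fields",
    "gen_response",
    "gen_sources",
    "simulate_dataset",
]


@dataclass
class CovariateSpec:
    mean: float
    sd: float
    n_waves: int = 4  # smooth low-order cosine field


def default_covariate_model() -> dict[str, CovariateSpec]:
    # magnitudes chosen to resemble real remote-sensing layers; arbitrary
    # post-standardization, but keep outputs on recognizable scales
    return {
        "AOD": CovariateSpec(540.8, 278.3),
        "ST": CovariateSpec(292.0, 13.5),
        "PS": CovariateSpec(1001.3, 22.1),
        "RH": CovariateSpec(69.7, 8.0),
        "PBLH": CovariateSpec(389.7, 140.6),
        "NDVI": CovariateSpec(62.0, 15.0),
        "DEM": CovariateSpec(138.3, 232.0),
        "FactDen": CovariateSpec(5.0, 2.0),
        "RoadDen": CovariateSpec(1.5, 0.6),
    }


def default_beta() -> dict[str, float]:
    return {
        "AOD": 0.30,
        "ST": -0.40,
        "PS": 0.60,
        "RH": 0.30,
        "PBLH": -0.60,
        "NDVI": -0.10,
        "DEM": -0.25,
        "FactDen": 0.30,
        "RoadDen": 0.0,
    }


@dataclass
class SimulationConfig:
    seed: int
    n_stations: int = 233
    region: tuple[float, float, float, float] = (0.0, 0.0, 400.0, 400.0)  # km
    k_true: int = 3
    beta_true: dict[str, float] = field(default_factory=default_beta)
    alpha_true: tuple[float, ...] = (1.2, 1.0, 0.8)
    true_eigen_indices: tuple[int, ...] | None = None  # default: 0..k_true-1
    sigma: float = 1.0
    intercept: float = 50.0
    covariate_model: dict[str, CovariateSpec] = field(default_factory=default_covariate_model)
    threshold: float = 0.10
    diagonal: float = 0.0
    n_factories: int = 60
    n_roads: int = 8
    road_steps: int = 30

    def __post_init__(self) -> None:
        if self.n_stations < 10:
            raise ValueError("n_stations must be at least 10")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")
        if self.k_true > self.n_stations - 2:
            raise ValueError("k_true must be at most n_stations - 2")
        if self.true_eigen_indices is None:
            self.true_eigen_indices = tuple(range(self.k_true))
        if len(self.alpha_true) != len(self.true_eigen_indices):
            raise ValueError("alpha_true length must match true_eigen_indices")

    @property
    def diagonal_length(self) -> float:
        x0, y0, x1, y1 = self.region
        return float(np.hypot(x1 - x0, y1 - y0))

    def _streams(self) -> dict[str, np.random.Generator]:
        names = ["stations", "covariates", "response", "sources", "coarse"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}


@dataclass
class SyntheticTruth:
    config: SimulationConfig
    stations: StationSet
    weights: SpatialWeights
    basis: EigenBasis
    candidates: CandidateSet
    beta_true: np.ndarray
    alpha_true: np.ndarray
    true_eigen_indices: list[int]
    sigma: float
    signal: np.ndarray  # noiseless response
    raster_stack: dict[str, RasterGrid] | None = None
    coarse_grids: dict[str, RasterGrid] | None = None
    source_points: np.ndarray | None = None
    source_lines: list[np.ndarray] | None = None


def gen_stations(config: SimulationConfig, max_attempts: int = 100_000) -> np.ndarray:
    """Uniform station draw with a minimum-separation rejection rule.

    Minimum pairwise distance is 0.1% of the region diagonal, which keeps
    the distance matrix strictly positive off-diagonal.
    """
    rng = config._streams()["stations"]
    x0, y0, x1, y1 = config.region
    if x1 <= x0 or y1 <= y0:
        raise ValueError("region must have positive extent")
    min_sep = 1e-3 * config.diagonal_length
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < config.n_stations:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "station rejection sampling failed; use a larger region or fewer stations"
            )
        cand = rng.uniform((x0, y0), (x1, y1))
        if pts and np.min(np.linalg.norm(np.array(pts) - cand, axis=1)) < min_sep:
            continue
        pts.append(cand)
    return np.array(pts)


def _field_params(rng: np.random.Generator, spec: CovariateSpec, region) -> dict:
    x0, y0, x1, y1 = region
    span = max(x1 - x0, y1 - y0)
    k = spec.n_waves
    amp = rng.uniform(0.5, 1.0, size=k)
    # wavelengths well below the region span: smooth fields that stay
    # distinguishable from the broadest eigenvector patterns
    wavelength = rng.uniform(0.10 * span, 0.45 * span, size=k)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=k)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=k)
    # RMS of a sum of cosines with independent phases: sqrt(sum amp^2 / 2)
    norm = np.sqrt(np.sum(amp**2) / 2.0)
    return {
        "amp": amp,
        "freq_x": np.cos(theta) / wavelength,
        "freq_y": np.sin(theta) / wavelength,
        "phase": phase,
        "norm": norm,
        "mean": spec.mean,
        "sd": spec.sd,
    }


def _eval_field(params: dict, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if params["sd"] == 0.0:
        return np.full(np.shape(x), params["mean"], dtype=float)
    arg = (
        2.0
        * np.pi
        * (
            np.multiply.outer(x, params["freq_x"])
            + np.multiply.outer(y, params["freq_y"])
        )
        + params["phase"]
    )
    raw = (np.cos(arg) * params["amp"]).sum(axis=-1)
    return params["mean"] + params["sd"] * raw / params["norm"]


def _all_field_params(config: SimulationConfig) -> dict[str, dict]:
    rng = config._streams()["covariates"]
    return {
        name: _field_params(rng, spec, config.region)
        for name, spec in config.covariate_model.items()
    }


def gen_covariate_fields(
    config: SimulationConfig,
    grid_spec: RasterGrid | None = None,
    stations_xy: np.ndarray | None = None,
):
    """Smooth seeded covariate fields on a grid and/or at station points.

    Returns (raster_stack, station_extracts); either element is None when
    the corresponding target was not requested.  Grid and station values
    come from the same analytic field, so raster extraction and direct
    evaluation agree up to cell discretization.
    """
    params = _all_field_params(config)
    stack = None
    if grid_spec is not None:
        pts = grid_spec.center_points()
        stack = {
            nm: grid_spec.like(
                _eval_field(p, pts[:, 0], pts[:, 1]).reshape(grid_spec.nrows, grid_spec.ncols)
            )
            for nm, p in params.items()
        }
    extracts = None
    if stations_xy is not None:
        xy = np.asarray(stations_xy, dtype=float)
        extracts = pd.DataFrame(
            {nm: _eval_field(p, xy[:, 0], xy[:, 1]) for nm, p in params.items()}
        )
    return stack, extracts


def gen_response(
    covariates: pd.DataFrame,
    basis: EigenBasis,
    config: SimulationConfig,
    indices: Sequence[int] | None = None,
):
    """Draw y = b0 + Z beta + sqrt(n-1) E_k alpha + eps from the truth.

    ``indices`` (default config.true_eigen_indices) must all pass the
    candidate threshold, otherwise the pipeline's selection rule could
    never recover them and the simulation is rejected.
    """
    indices = list(config.true_eigen_indices if indices is None else indices)
    candidates = select_candidates(basis, threshold=config.threshold)
    outside = [j for j in indices if j not in candidates.indices]
    if outside:
        raise ValueError(
            f"true eigenvector indices {outside} fail the candidate threshold "
            f"{config.threshold}; unrecoverable by the selection rule"
        )
    rng = config._streams()["response"]
    names = [nm for nm in covariates.columns if nm in config.beta_true]
    beta = np.array([config.beta_true[nm] for nm in names])
    X = covariates[names].to_numpy(dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    n = len(covariates)
    E = basis.eigenvectors[:, indices] * np.sqrt(n - 1)
    alpha = np.asarray(config.alpha_true, dtype=float)
    signal = config.intercept + Z @ beta + E @ alpha
    y = signal + config.sigma * rng.standard_normal(n)
    return y, signal, beta, alpha


def gen_sources(config: SimulationConfig):
    """Seeded factory points and random-walk road polylines in the region."""
    rng = config._streams()["sources"]
    x0, y0, x1, y1 = config.region
    points = rng.uniform((x0, y0), (x1, y1), size=(config.n_factories, 2))
    lines = []
    step = config.diagonal_length / max(config.road_steps, 1) / 4.0
    for _ in range(config.n_roads):
        pos = rng.uniform((x0, y0), (x1, y1))
        heading = rng.uniform(0.0, 2.0 * np.pi)
        verts = [pos.copy()]
        for _ in range(config.road_steps):
            heading += rng.normal(0.0, 0.35)
            pos = pos + step * np.array([np.cos(heading), np.sin(heading)])
            pos = np.clip(pos, (x0, y0), (x1, y1))
            verts.append(pos.copy())
        lines.append(np.array(verts))
    return points, lines


def default_grid_spec(config: SimulationConfig, cell_size: float = 10.0) -> RasterGrid:
    x0, y0, x1, y1 = config.region
    ncols = int(np.ceil((x1 - x0) / cell_size))
    nrows = int(np.ceil((y1 - y0) / cell_size))
    return RasterGrid.empty(x0, y1, cell_size, ncols, nrows, crs_label="synthetic-km")


def gen_coarse_grids(
    config: SimulationConfig, names: Sequence[str] = ("ST", "PS", "RH", "PBLH"), factor: float = 8.0
) -> dict[str, RasterGrid]:
    """Coarse-resolution versions of selected fields, plus sampling noise."""
    rng = config._streams()["coarse"]
    fine = default_grid_spec(config)
    coarse = RasterGrid.empty(
        fine.x0, fine.y0, fine.cell_size * factor,
        int(np.ceil(fine.ncols / factor)), int(np.ceil(fine.nrows / factor)),
        crs_label=fine.crs_label,
    )
    params = _all_field_params(config)
    out = {}
    pts = coarse.center_points()
    for nm in names:
        if nm not in params:
            continue
        vals = _eval_field(params[nm], pts[:, 0], pts[:, 1])
        vals = vals + 0.02 * params[nm]["sd"] * rng.standard_normal(len(vals))
        out[nm] = coarse.like(vals.reshape(coarse.nrows, coarse.ncols))
    return out


def simulate_dataset(config: SimulationConfig, include_rasters: bool = False) -> SyntheticTruth:
    """Full ground-truth scene: stations, weights, basis, response, extras."""
    xy = gen_stations(config)
    weights = build_weights(xy, diagonal=config.diagonal)
    basis = eigendecompose(weights.C1)
    candidates = select_candidates(basis, threshold=config.threshold)
    grid_spec = default_grid_spec(config) if include_rasters else None
    stack, covariates = gen_covariate_fields(config, grid_spec=grid_spec, stations_xy=xy)
    y, signal, beta, alpha = gen_response(covariates, basis, config)
    stations = StationSet(
        ids=np.array([f"S{i:04d}" for i in range(config.n_stations)]),
        xy=xy,
        values=y,
        covariates=covariates,
    )
    points, lines = (None, None)
    coarse = None
    if include_rasters:
        points, lines = gen_sources(config)
        coarse = gen_coarse_grids(config)
    return SyntheticTruth(
        config=config,
        stations=stations,
        weights=weights,
        basis=basis,
        candidates=candidates,
        beta_true=beta,
        alpha_true=alpha,
        true_eigen_indices=list(config.true_eigen_indices),
        sigma=config.sigma,
        signal=signal,
        raster_stack=stack,
        coarse_grids=coarse,
        source_points=points,
        source_lines=lines,
    )
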