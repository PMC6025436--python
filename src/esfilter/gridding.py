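"""Raster preprocessing and map production.

Raster convention: origin (x0, y0) is the upper-left corner, values are
row-major with row 0 at the top; the center of cell (i, j) sits at
(x0 + (j + 0.5) * cell, y0 - (i + 0.5) * cell).  Missing cells are NaN in
memory and a sentinel on disk (ESRI ASCII grid).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg, optimize
from scipy.spatial.distance import cdist, pdist, squareform

from .cross_validation import extend_to_points
from .eigenfilter import EigenBasis
from .regression import ESFRModel
from .spatial_weights import SpatialWeights
from .stations import StationSet

__all__ = [
    "RasterGrid",
    "ExposureGrid",
    "SphericalVariogram",
    "ordinary_kriging",
    "kriging_predict",
    "fit_spherical_variogram",
    "bilinear_resample",
    "extract_at_stations",
    "predict_map",
    "classify_levels",
]


@dataclass
class RasterGrid:
    x0: float  # upper-left corner x
    y0: float  # upper-left corner y
    cell_size: float
    ncols: int
    nrows: int
    values: np.ndarray = None
    nodata: float = -9999.0
    crs_label: str = ""

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.values is None:
            self.values = np.full((self.nrows, self.ncols), np.nan)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise ValueError(
                f"values shape {self.values.shape} != ({self.nrows}, {self.ncols})"
            )

    @classmethod
    def empty(cls, x0, y0, cell_size, ncols, nrows, crs_label="") -> "RasterGrid":
        return cls(x0, y0, cell_size, ncols, nrows, crs_label=crs_label)

    def like(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=float))

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.ncols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 - (np.arange(self.nrows) + 0.5) * self.cell_size

    def center_points(self) -> np.ndarray:
        """(nrows * ncols, 2) cell-center coordinates, row-major."""
        xx, yy = np.meshgrid(self.x_centers, self.y_centers)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def spec_dict(self) -> dict:
        return {
            "x0": self.x0,
            "y0": self.y0,
            "cell_size": self.cell_size,
            "ncols": self.ncols,
            "nrows": self.nrows,
            "nodata": self.nodata,
            "crs_label": self.crs_label,
        }

    def write_ascii(self, path) -> None:
        vals = np.where(np.isfinite(self.values), self.values, self.nodata)
        header = (
            f"ncols {self.ncols}\n"
            f"nrows {self.nrows}\n"
            f"xllcorner {self.x0!r}\n"
            f"yllcorner {(self.y0 - self.nrows * self.cell_size)!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path, crs_label: str = "") -> "RasterGrid":
        header: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        ncols, nrows = int(header["ncols"]), int(header["nrows"])
        vals = vals.reshape(nrows, ncols)
        nodata = header.get("nodata_value", -9999.0)
        vals = np.where(vals == nodata, np.nan, vals)
        cell = header["cellsize"]
        return cls(
            x0=header["xllcorner"],
            y0=header["yllcorner"] + nrows * cell,
            cell_size=cell,
            ncols=ncols,
            nrows=nrows,
            values=vals,
            nodata=nodata,
            crs_label=crs_label,
        )


@dataclass
class ExposureGrid:
    prediction: RasterGrid
    filter_surface: RasterGrid
    levels: RasterGrid
    area_pct: dict[int, float] = field(default_factory=dict)


@dataclass
class SphericalVariogram:
    """Spherical semivariance model; gamma(0) = 0 (exact interpolation)."""

    nugget: float
    sill: float
    range: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.range <= 0:
            raise ValueError("variogram range must be positive")
        if not (self.sill > self.nugget >= 0):
            raise ValueError("need sill > nugget >= 0")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        hr = np.minimum(h / self.range, 1.0)
        g = self.nugget + (self.sill - self.nugget) * (1.5 * hr - 0.5 * hr**3)
        return np.where(h == 0.0, 0.0, g)


def kriging_predict(
    xy: np.ndarray,
    values: np.ndarray,
    variogram: SphericalVariogram,
    targets_xy: np.ndarray,
    return_weights: bool = False,
):
    """Ordinary kriging at arbitrary target points.

    Solves [Gamma 1; 1' 0][w; mu] = [gamma0; 1] per target (weights sum
    to 1 by the unbiasedness constraint); prediction is w' values.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    k = len(xy)
    if k < 3:
        raise ValueError(f"ordinary kriging needs at least 3 points, got {k}")
    D = squareform(pdist(xy))
    if np.any(D[~np.eye(k, dtype=bool)] == 0.0):
        raise ValueError("duplicate kriging points make the system singular")
    A = np.empty((k + 1, k + 1))
    A[:k, :k] = variogram(D)
    A[k, :k] = A[:k, k] = 1.0
    A[k, k] = 0.0
    lu = linalg.lu_factor(A)
    targets_xy = np.atleast_2d(np.asarray(targets_xy, dtype=float))
    g = variogram(cdist(targets_xy, xy))
    rhs = np.hstack([g, np.ones((len(targets_xy), 1))])
    sol = linalg.lu_solve(lu, rhs.T).T
    w = sol[:, :k]
    pred = w @ values
    if return_weights:
        return pred, w
    return pred


def ordinary_kriging(
    points, variogram: SphericalVariogram, targets: RasterGrid
) -> RasterGrid:
    """Krige scattered (x, y, value) points onto every cell of a target grid."""
    pts = np.asarray(points, dtype=float)
    pred = kriging_predict(pts[:, :2], pts[:, 2], variogram, targets.center_points())
    return targets.like(pred.reshape(targets.nrows, targets.ncols))


def fit_spherical_variogram(
    points, n_bins: int = 12, min_sill: float = 1e-12
) -> SphericalVariogram:
    """Fit a spherical model to the binned empirical semivariogram.

    Distance bins span (0, max distance / 2]; bin semivariance is the mean
    of squared value differences / 2; the model is fitted by weighted least
    squares with bin pair-counts as weights.  A constant field returns a
    degenerate near-zero variogram rather than failing.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 10:
        raise ValueError(f"variogram fit needs at least 10 points, got {len(pts)}")
    xy, vals = pts[:, :2], pts[:, 2]
    if np.ptp(vals) == 0.0:
        return SphericalVariogram(0.0, min_sill, 1.0, degenerate=True)
    d = pdist(xy)
    dv2 = pdist(vals[:, None], metric="sqeuclidean") / 2.0
    hmax = d.max() / 2.0
    edges = np.linspace(0.0, hmax, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    keep = d <= hmax
    h_emp, g_emp, wts = [], [], []
    for b in range(n_bins):
        m = keep & (which == b)
        if m.sum() == 0:
            continue
        h_emp.append(d[m].mean())
        g_emp.append(dv2[m].mean())
        wts.append(m.sum())
    h_emp, g_emp = np.array(h_emp), np.array(g_emp)
    wts = np.sqrt(np.array(wts, dtype=float))

    var0 = float(vals.var(ddof=1))

    def resid(theta):
        nugget, psill, rng = theta
        model = SphericalVariogram(max(nugget, 0.0), max(nugget, 0.0) + max(psill, min_sill), max(rng, 1e-9))
        return wts * (model(h_emp) - g_emp)

    x0 = np.array([0.0, var0, hmax])
    res = optimize.least_squares(
        resid,
        x0,
        bounds=([0.0, min_sill, 1e-9], [np.inf, np.inf, np.inf]),
        method="trf",
    )
    nugget, psill, rng = res.x
    return SphericalVariogram(float(nugget), float(nugget + psill), float(rng))


def bilinear_resample(src: RasterGrid, dst_spec: RasterGrid) -> RasterGrid:
    """Interpolate src cell-center values onto dst cell centers.

    A destination center outside the source center lattice, or with any
    NaN corner, becomes nodata.
    """
    pts = dst_spec.center_points()
    # fractional position in the source center lattice
    gx = (pts[:, 0] - (src.x0 + 0.5 * src.cell_size)) / src.cell_size
    gy = ((src.y0 - 0.5 * src.cell_size) - pts[:, 1]) / src.cell_size
    # clamp the base index so a center exactly on the last lattice node
    # interpolates from the final cell pair with fraction 1
    j0 = np.clip(np.floor(gx).astype(int), 0, src.ncols - 2)
    i0 = np.clip(np.floor(gy).astype(int), 0, src.nrows - 2)
    fx = gx - j0
    fy = gy - i0
    inside = (gx >= 0) & (gx <= src.ncols - 1) & (gy >= 0) & (gy <= src.nrows - 1)
    out = np.full(len(pts), np.nan)
    if inside.any():
        j0i, i0i = j0[inside], i0[inside]
        v00 = src.values[i0i, j0i]
        v01 = src.values[i0i, j0i + 1]
        v10 = src.values[i0i + 1, j0i]
        v11 = src.values[i0i + 1, j0i + 1]
        fxi, fyi = fx[inside], fy[inside]
        top = v00 * (1 - fxi) + v01 * fxi
        bot = v10 * (1 - fxi) + v11 * fxi
        out[inside] = top * (1 - fyi) + bot * fyi
    return dst_spec.like(out.reshape(dst_spec.nrows, dst_spec.ncols))


def extract_at_stations(grid: RasterGrid, stations: StationSet):
    """Nearest-cell value per station.

    Returns (values, dropped_ids): stations outside the grid or on nodata
    get NaN and are listed in dropped_ids (logged, not raised).
    """
    col = np.floor((stations.xy[:, 0] - grid.x0) / grid.cell_size).astype(int)
    row = np.floor((grid.y0 - stations.xy[:, 1]) / grid.cell_size).astype(int)
    vals = np.full(len(stations), np.nan)
    inside = (col >= 0) & (col < grid.ncols) & (row >= 0) & (row < grid.nrows)
    vals[inside] = grid.values[row[inside], col[inside]]
    dropped = list(stations.ids[~np.isfinite(vals)])
    if dropped:
        warnings.warn(f"{len(dropped)} stations dropped (outside grid or nodata)", stacklevel=2)
    return vals, dropped


def classify_levels(prediction: RasterGrid, standard: float = 35.0, multipliers=(1.0, 1.5, 2.0)):
    """Four exposure levels relative to a standard; boundary belongs below.

    level 1: v <= s; level 2: s < v <= 1.5 s; level 3: 1.5 s < v <= 2 s;
    level 4: v > 2 s.  Area percentages are over valid cells only.
    """
    v = prediction.values
    valid = np.isfinite(v)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid cells to classify")
    cuts = [m * standard for m in multipliers]
    levels = np.full(v.shape, np.nan)
    levels[valid & (v <= cuts[0])] = 1
    levels[valid & (v > cuts[0]) & (v <= cuts[1])] = 2
    levels[valid & (v > cuts[1]) & (v <= cuts[2])] = 3
    levels[valid & (v > cuts[2])] = 4
    area_pct = {
        lev: float(100.0 * np.sum(levels[valid] == lev) / n_valid) for lev in (1, 2, 3, 4)
    }
    return prediction.like(levels), area_pct


def predict_map(
    model: ESFRModel,
    covariate_stack: dict[str, RasterGrid],
    basis: EigenBasis | None,
    weights: SpatialWeights,
    stations: StationSet,
    standard: float = 35.0,
    multipliers=(1.0, 1.5, 2.0),
) -> ExposureGrid:
    """Apply a fitted model across a raster stack.

    Per valid cell: standardize covariates with the model's stored
    (mean, sd), Nystrom-extend each selected eigenvector to the cell
    center, predict on the raw response scale, and keep the spatial-filter
    contribution (standardized-response scale) as a separate surface.
    """
    missing = [nm for nm in model.covariate_names if nm not in covariate_stack]
    if missing:
        raise ValueError(f"covariate stack missing layers: {missing}")
    grids = [covariate_stack[nm] for nm in model.covariate_names]
    template = grids[0]
    for g in grids[1:]:
        if not g.aligned_with(template):
            raise ValueError("covariate stack grids are not aligned")

    stackvals = np.stack([g.values.ravel() for g in grids], axis=1)
    valid = np.all(np.isfinite(stackvals), axis=1)
    pts = template.center_points()[valid]

    zpred = np.full(valid.sum(), model.intercept)
    for k, nm in enumerate(model.covariate_names):
        mu, sd = model.standardization[nm]
        zpred += model.beta[k] * (stackvals[valid, k] - mu) / sd

    filt = np.zeros(valid.sum())
    if model.is_spatial:
        E = extend_to_points(
            basis,
            weights.C0,
            stations.xy,
            weights.r,
            pts,
            model.eigen_indices,
            diagonal=weights.diagonal,
        )
        filt = E @ model.alpha
        zpred += filt

    mu_y, sd_y = model.standardization["__response__"]
    pred = np.full(template.nrows * template.ncols, np.nan)
    pred[valid] = mu_y + sd_y * zpred
    fsurf = np.full(template.nrows * template.ncols, np.nan)
    fsurf[valid] = filt

    prediction = template.like(pred.reshape(template.nrows, template.ncols))
    filter_surface = template.like(fsurf.reshape(template.nrows, template.ncols))
    levels, area_pct = classify_levels(prediction, standard=standard, multipliers=multipliers)
    return ExposureGrid(
        prediction=prediction,
        filter_surface=filter_surface,
        levels=levels,
        area_pct=area_pct,
    )


def write_grid_spec(grid: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        json.dump(grid.spec_dict(), fh, indent=2)
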