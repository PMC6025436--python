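"""Pollution-source density surfaces.

Point and line densities are computed in a disk buffer (default radius
24 km) around each cell center, normalized by the buffer area pi r^2.
The composite index is the mean of the min-max normalized road and
factory densities; the area normalization cancels under min-max
normalization, so the index is insensitive to that convention.
"""

from __future__ import annotations

import json

import numpy as np
from scipy.spatial.distance import cdist

from .gridding import RasterGrid

__all__ = [
    "point_density",
    "line_density",
    "minmax_normalize",
    "composite_source_density",
    "dedup_points",
    "read_geojson_features",
]


def dedup_points(points: np.ndarray) -> np.ndarray:
    """Exact-coordinate de-duplication (order of first occurrence kept)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return pts.reshape(0, 2)
    _, first = np.unique(pts, axis=0, return_index=True)
    return pts[np.sort(first)]


def point_density(points, grid_spec: RasterGrid, radius: float = 24.0) -> RasterGrid:
    """Count of points within ``radius`` of each cell center, per unit area."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    centers = grid_spec.center_points()
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        counts = np.zeros(len(centers))
    else:
        counts = (cdist(centers, pts) <= radius).sum(axis=1).astype(float)
    dens = counts / (np.pi * radius**2)
    return grid_spec.like(dens.reshape(grid_spec.nrows, grid_spec.ncols))


def _clipped_lengths(centers: np.ndarray, p0: np.ndarray, p1: np.ndarray, radius: float):
    """Length of each segment inside the disk around each center.

    Solves |p0 + t (p1 - p0) - c|^2 = r^2 per (center, segment) pair and
    clips the solution interval to t in [0, 1]; analytic, no sampling.
    """
    d = p1 - p0  # (s, 2)
    L2 = np.sum(d * d, axis=1)
    L = np.sqrt(L2)
    f = p0[None, :, :] - centers[:, None, :]  # (m, s, 2)
    b = 2.0 * np.sum(f * d[None, :, :], axis=2)
    cc = np.sum(f * f, axis=2) - radius**2
    disc = b**2 - 4.0 * L2[None, :] * cc
    hit = disc > 0
    sq = np.sqrt(np.where(hit, disc, 0.0))
    t0 = np.clip((-b - sq) / (2.0 * L2[None, :]), 0.0, 1.0)
    t1 = np.clip((-b + sq) / (2.0 * L2[None, :]), 0.0, 1.0)
    return np.where(hit, (t1 - t0) * L[None, :], 0.0)


def line_density(lines, grid_spec: RasterGrid, radius: float = 24.0) -> RasterGrid:
    """Summed clipped segment length inside the disk buffer, per unit area."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    centers = grid_spec.center_points()
    total = np.zeros(len(centers))
    n_degenerate = 0
    segs0, segs1 = [], []
    for line in lines:
        v = np.asarray(line, dtype=float)
        a, bpt = v[:-1], v[1:]
        keep = np.any(a != bpt, axis=1)
        n_degenerate += int((~keep).sum())
        segs0.append(a[keep])
        segs1.append(bpt[keep])
    if segs0:
        p0 = np.concatenate(segs0)
        p1 = np.concatenate(segs1)
        if len(p0):
            total = _clipped_lengths(centers, p0, p1, radius).sum(axis=1)
    grid = grid_spec.like((total / (np.pi * radius**2)).reshape(grid_spec.nrows, grid_spec.ncols))
    if n_degenerate:
        import warnings

        warnings.warn(f"skipped {n_degenerate} zero-length segments", stacklevel=2)
    return grid


def minmax_normalize(grid: RasterGrid) -> RasterGrid:
    """Map valid cells to [0, 1]: (x - min)/(max - min); nodata preserved."""
    v = grid.values
    valid = np.isfinite(v)
    vals = v[valid]
    if vals.size < 2 or vals.max() == vals.min():
        raise ValueError("grid needs at least 2 distinct valid values to normalize")
    out = np.full(v.shape, np.nan)
    out[valid] = (vals - vals.min()) / (vals.max() - vals.min())
    return grid.like(out)


def composite_source_density(road_norm: RasterGrid, fact_norm: RasterGrid) -> RasterGrid:
    """Cellwise mean of the two normalized densities; nodata propagates."""
    if not road_norm.aligned_with(fact_norm):
        raise ValueError("density grids are not aligned")
    return road_norm.like((road_norm.values + fact_norm.values) / 2.0)


def read_geojson_features(path):
    """Extract Point and LineString/MultiLineString coordinates from GeoJSON.

    Returns (points, lines): an (m, 2) array and a list of (k, 2) arrays.
    """
    with open(path) as fh:
        doc = json.load(fh)
    feats = doc["features"] if doc.get("type") == "FeatureCollection" else [doc]
    points, lines = [], []
    for feat in feats:
        geom = feat.get("geometry", feat)
        gtype = geom.get("type")
        coords = geom.get("coordinates")
        if gtype == "Point":
            points.append(coords)
        elif gtype == "MultiPoint":
            points.extend(coords)
        elif gtype == "LineString":
            lines.append(np.asarray(coords, dtype=float))
        elif gtype == "MultiLineString":
            lines.extend(np.asarray(c, dtype=float) for c in coords)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return pts, lines
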