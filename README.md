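# esfilter

Eigenvector spatial filtering regression (ESF) for station-based exposure
modeling and mapping.

Monitoring-station measurements of an environmental exposure (e.g. fine
particulate matter) are regressed on gridded covariates plus a *spatial
filter*: a linear combination of eigenvectors of the double-centered,
distance-kernel spatial weights matrix over the station network. The filter
absorbs spatial autocorrelation that would otherwise contaminate OLS
residuals, improving fit and out-of-sample prediction, and yields a mappable
spatial-effect surface.

## What is implemented

- **spatial_weights** — Euclidean distances, kernel range `r` from the
  longest minimum-spanning-tree edge, exponential decay kernel
  `exp(-d/r)` (zero diagonal, configurable), double centering
  `C1 = (I - 11'/n) C0 (I - 11'/n)`.
- **eigenfilter** — full spectral decomposition of `C1` with a reproducible
  sign convention; candidate selection by eigenvalue ratio
  `lambda_i / lambda_1 >= 0.10`; Moran coefficient of arbitrary vectors.
- **regression** — greedy forward stepwise selection of eigenvectors on
  adjusted R² with all covariates forced in; OLS on z-scored variables;
  pruning of insignificant covariates (p > 0.10) followed by one re-selection
  pass; adjusted R², RSE, MAPE and AICc on the raw response scale; the
  non-spatial GMLR baseline.
- **diagnostics** — global Moran's I with randomization-assumption moments
  and a one-sided normal p-value; residual Moran's I; Pearson correlation
  screening tables with significance markers.
- **cross_validation** — leave-one-out CV with full per-fold rebuilds
  (weights, eigenbasis, selection, fit) and Nyström extension of selected
  eigenvectors to held-out locations.
- **gridding** — ASCII-grid rasters; ordinary kriging with a spherical
  variogram (plus a weighted-least-squares variogram fitter); bilinear
  resampling; nearest-cell station extraction; model application across a
  raster stack (prediction, filter surface, 4-level classification and area
  percentages).
- **sources** — disk-buffer point and line densities (analytic
  segment-circle clipping), min-max normalization and the composite
  source-density index.
- **synthetic_data** — seeded generators for station networks, smooth
  covariate fields, filter-bearing responses with known coefficients,
  coarse grids and point/line source geometries; every pipeline stage is
  testable offline with known ground truth.

## CLI

```sh
esfilter simulate --seed 1 --n-stations 100 --out scene/
esfilter fit --stations scene/stations.csv --out fit/
esfilter cv --stations scene/stations.csv --out cv/
esfilter diagnose --stations scene/stations.csv --out diag/
esfilter sources --geojson scene/sources.geojson --grid grid.json --out dens/
esfilter predict-map --stations scene/stations.csv --stack stack.json --out map/
```

`fit` writes `report.json`/`report.md` with the standardized-coefficient
table ("/" marks pruned covariates), the GMLR-vs-ESFR metric comparison
with percent changes, and residual Moran's I for both models.

Station CSVs have columns `station_id,x,y,value,<covariate...>` with planar
coordinates (project lon/lat first). Rasters are ESRI ASCII grids; source
geometries are GeoJSON Points and LineStrings.

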