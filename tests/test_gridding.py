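import numpy as np
import pytest

from esfilter.cross_validation import kernel_row, nystrom_extend
from esfilter.gridding import (
    RasterGrid,
    SphericalVariogram,
    bilinear_resample,
    classify_levels,
    extract_at_stations,
    fit_spherical_variogram,
    kriging_predict,
    ordinary_kriging,
    predict_map,
)
from esfilter.pipeline import fit_pipeline
from esfilter.stations import StationSet
from esfilter.synthetic_data import (
    SimulationConfig,
    default_grid_spec,
    gen_covariate_fields,
)
from oracles import kriging_dense_solve


@pytest.fixture
def grid4x4():
    return RasterGrid.empty(0.0, 40.0, 10.0, 4, 4)


class TestRasterGrid:
    def test_centers(self, grid4x4):
        np.testing.assert_allclose(grid4x4.x_centers, [5.0, 15.0, 25.0, 35.0])
        np.testing.assert_allclose(grid4x4.y_centers, [35.0, 25.0, 15.0, 5.0])

    def test_ascii_round_trip(self, tmp_path, rng):
        g = RasterGrid(0.0, 30.0, 5.0, 4, 6, values=rng.normal(size=(6, 4)))
        g.values[2, 1] = np.nan
        g.write_ascii(tmp_path / "g.asc")
        back = RasterGrid.read_ascii(tmp_path / "g.asc")
        assert back.aligned_with(g)
        np.testing.assert_allclose(back.values, g.values, atol=1e-9, equal_nan=True)


class TestOrdinaryKriging:
    def test_exact_interpolator_with_zero_nugget(self, rng):
        xy = rng.uniform(0, 10, size=(6, 2))
        vals = rng.normal(size=6)
        vg = SphericalVariogram(0.0, 2.0, 8.0)
        pred = kriging_predict(xy, vals, vg, xy)
        np.testing.assert_allclose(pred, vals, atol=1e-8)

    def test_weights_sum_to_one(self, rng):
        xy = rng.uniform(0, 10, size=(7, 2))
        vals = rng.normal(size=7)
        vg = SphericalVariogram(0.3, 1.5, 6.0)
        _, w = kriging_predict(xy, vals, vg, rng.uniform(0, 10, size=(5, 2)), return_weights=True)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-8)

    def test_matches_dense_solve(self, rng):
        xy = rng.uniform(0, 10, size=(4, 2))
        vals = rng.normal(size=4)
        vg = SphericalVariogram(0.1, 2.0, 7.0)
        target = np.array([4.2, 5.1])
        got = kriging_predict(xy, vals, vg, target[None, :])[0]
        want, _ = kriging_dense_solve(xy, vals, lambda h: float(vg(np.array(h))), target)
        assert got == pytest.approx(want, rel=1e-10)

    def test_constant_field_reproduced(self, rng, grid4x4):
        xy = rng.uniform(0, 40, size=(8, 2))
        pts = np.column_stack([xy, np.full(8, 3.7)])
        out = ordinary_kriging(pts, SphericalVariogram(0.2, 1.0, 20.0), grid4x4)
        np.testing.assert_allclose(out.values, 3.7, atol=1e-8)

    def test_duplicate_points_rejected(self):
        xy = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="duplicate"):
            kriging_predict(xy, np.zeros(3), SphericalVariogram(0.0, 1.0, 5.0), xy)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kriging_predict(
                np.zeros((2, 2)), np.zeros(2), SphericalVariogram(0.0, 1.0, 5.0), np.zeros((1, 2))
            )


class TestVariogram:
    def test_spherical_shape(self):
        vg = SphericalVariogram(0.5, 2.0, 10.0)
        assert vg(np.array([0.0]))[0] == 0.0
        assert vg(np.array([10.0]))[0] == pytest.approx(2.0)
        assert vg(np.array([100.0]))[0] == pytest.approx(2.0)
        assert vg(np.array([5.0]))[0] == pytest.approx(0.5 + 1.5 * (0.75 - 0.5 * 0.125))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            SphericalVariogram(1.0, 0.5, 10.0)
        with pytest.raises(ValueError):
            SphericalVariogram(0.0, 1.0, -1.0)

    def test_pure_nugget_data(self, rng):
        xy = rng.uniform(0, 100, size=(150, 2))
        vals = rng.normal(size=150)
        pts = np.column_stack([xy, vals])
        vg = fit_spherical_variogram(pts)
        assert vg.sill == pytest.approx(vals.var(ddof=1), rel=0.25)
        # no usable spatial structure: semivariance near the sill at short range
        assert vg(np.array([5.0]))[0] > 0.5 * vals.var(ddof=1)

    def test_recovers_known_model(self):
        true = SphericalVariogram(0.0, 1.0, 30.0)
        sills, ranges = [], []
        for seed in range(5):
            g = np.random.default_rng(seed)
            xy = g.uniform(0, 100, size=(220, 2))
            d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
            cov = true.sill - np.asarray(true(d))
            np.fill_diagonal(cov, true.sill)
            vals = g.multivariate_normal(np.zeros(len(xy)), cov + 1e-10 * np.eye(len(xy)))
            vg = fit_spherical_variogram(np.column_stack([xy, vals]))
            sills.append(vg.sill)
            ranges.append(vg.range)
        assert np.mean(sills) == pytest.approx(true.sill, rel=0.30)
        assert np.mean(ranges) == pytest.approx(true.range, rel=0.30)

    def test_constant_field_degenerate(self, rng):
        pts = np.column_stack([rng.uniform(0, 10, size=(12, 2)), np.full(12, 2.0)])
        vg = fit_spherical_variogram(pts)
        assert vg.degenerate
        assert vg.nugget == 0.0

    def test_too_few_points(self, rng):
        pts = np.column_stack([rng.uniform(0, 10, size=(5, 2)), rng.normal(size=5)])
        with pytest.raises(ValueError, match="at least 10"):
            fit_spherical_variogram(pts)


class TestBilinearResample:
    def test_node_identity(self, rng):
        src = RasterGrid(0.0, 40.0, 10.0, 4, 4, values=rng.normal(size=(4, 4)))
        out = bilinear_resample(src, src)
        np.testing.assert_allclose(out.values, src.values, atol=1e-12)

    def test_midpoint_average(self):
        src = RasterGrid(0.0, 20.0, 10.0, 2, 2, values=np.array([[1.0, 2.0], [3.0, 4.0]]))
        dst = RasterGrid.empty(5.0, 15.0, 10.0, 1, 1)  # center (10, 10) = src midpoint
        out = bilinear_resample(src, dst)
        assert out.values[0, 0] == pytest.approx(2.5)

    def test_matches_two_stage_formula(self, rng):
        src = RasterGrid(0.0, 50.0, 10.0, 5, 5, values=rng.normal(size=(5, 5)))
        x, y = 23.7, 31.2
        dst = RasterGrid.empty(x - 0.5, y + 0.5, 1.0, 1, 1)
        out = bilinear_resample(src, dst)
        # manual: surrounding centers and two-stage interpolation
        gx = (x - 5.0) / 10.0
        gy = (45.0 - y) / 10.0
        j0, i0 = int(np.floor(gx)), int(np.floor(gy))
        fx, fy = gx - j0, gy - i0
        top = src.values[i0, j0] * (1 - fx) + src.values[i0, j0 + 1] * fx
        bot = src.values[i0 + 1, j0] * (1 - fx) + src.values[i0 + 1, j0 + 1] * fx
        assert out.values[0, 0] == pytest.approx(top * (1 - fy) + bot * fy, rel=1e-12)

    def test_no_overshoot(self, rng):
        src = RasterGrid(0.0, 80.0, 10.0, 8, 8, values=rng.normal(size=(8, 8)))
        dst = RasterGrid.empty(5.0, 75.0, 3.0, 20, 20)
        out = bilinear_resample(src, dst)
        valid = out.values[np.isfinite(out.values)]
        assert valid.min() >= src.values.min() - 1e-12
        assert valid.max() <= src.values.max() + 1e-12

    def test_outside_becomes_nodata(self, rng):
        src = RasterGrid(0.0, 20.0, 10.0, 2, 2, values=rng.normal(size=(2, 2)))
        dst = RasterGrid.empty(100.0, 120.0, 10.0, 2, 2)
        out = bilinear_resample(src, dst)
        assert np.all(~np.isfinite(out.values))

    def test_nan_corner_propagates(self):
        vals = np.array([[1.0, np.nan], [3.0, 4.0]])
        src = RasterGrid(0.0, 20.0, 10.0, 2, 2, values=vals)
        dst = RasterGrid.empty(5.0, 15.0, 10.0, 1, 1)
        out = bilinear_resample(src, dst)
        assert np.isnan(out.values[0, 0])


class TestExtractAtStations:
    def _stations(self, xy):
        import pandas as pd

        n = len(xy)
        return StationSet(
            ids=np.array([f"s{i}" for i in range(n)]),
            xy=xy,
            values=np.arange(n, dtype=float) + 1,
            covariates=pd.DataFrame({"c": np.zeros(n)}),
        )

    def test_cell_center_value(self, grid4x4, rng):
        grid = grid4x4.like(rng.normal(size=(4, 4)))
        st = self._stations(np.array([[5.0, 35.0], [25.0, 15.0], [35.0, 5.0]]))
        vals, dropped = extract_at_stations(grid, st)
        np.testing.assert_allclose(vals, [grid.values[0, 0], grid.values[2, 2], grid.values[3, 3]])
        assert dropped == []

    def test_nodata_station_dropped(self, grid4x4, rng):
        grid = grid4x4.like(rng.normal(size=(4, 4)))
        grid.values[0, 0] = np.nan
        st = self._stations(np.array([[5.0, 35.0], [25.0, 15.0], [500.0, 5.0]]))
        with pytest.warns(UserWarning, match="dropped"):
            vals, dropped = extract_at_stations(grid, st)
        assert dropped == ["s0", "s2"]
        assert np.isnan(vals[0]) and np.isnan(vals[2])

    def test_index_arithmetic(self, rng):
        grid = RasterGrid(10.0, 90.0, 7.0, 6, 9, values=rng.normal(size=(9, 6)))
        xy = rng.uniform([11, 40], [50, 89], size=(5, 2))
        st = self._stations(xy)
        vals, _ = extract_at_stations(grid, st)
        for k, (x, y) in enumerate(xy):
            col = int(np.floor((x - 10.0) / 7.0))
            row = int(np.floor((90.0 - y) / 7.0))
            assert vals[k] == grid.values[row, col]


class TestClassifyLevels:
    def test_boundaries(self):
        g = RasterGrid(0, 20, 10, 2, 2, values=np.array([[35.0, 52.5], [70.0, 70.0001]]))
        levels, _ = classify_levels(g)
        np.testing.assert_allclose(levels.values, [[1, 2], [3, 4]])

    def test_area_percentages(self):
        g = RasterGrid(0, 20, 10, 2, 2, values=np.array([[10.0, 40.0], [60.0, 80.0]]))
        _, pct = classify_levels(g)
        assert pct == {1: 25.0, 2: 25.0, 3: 25.0, 4: 25.0}

    def test_percentages_sum_to_100(self, rng):
        vals = rng.uniform(0, 100, size=(9, 9))
        vals[0, :3] = np.nan
        g = RasterGrid(0, 90, 10, 9, 9, values=vals)
        _, pct = classify_levels(g)
        assert sum(pct.values()) == pytest.approx(100.0, abs=0.1)

    def test_all_nodata_rejected(self):
        g = RasterGrid.empty(0, 20, 10, 2, 2)
        with pytest.raises(ValueError, match="no valid cells"):
            classify_levels(g)


@pytest.fixture(scope="module")
def scene():
    cfg = SimulationConfig(seed=21, n_stations=40, sigma=1.0, region=(0, 0, 200, 200))
    from esfilter.synthetic_data import simulate_dataset

    truth = simulate_dataset(cfg)
    grid = RasterGrid.empty(0.0, 200.0, 10.0, 20, 20)
    stack, _ = gen_covariate_fields(cfg, grid_spec=grid)
    pf = fit_pipeline(truth.stations, prune=False)
    return truth, stack, pf


class TestPredictMap:
    def test_filter_surface_zero_without_eigens(self, scene):
        truth, stack, _ = scene
        from esfilter.regression import fit_gmlr

        gmlr = fit_gmlr(truth.stations.values, truth.stations.covariates)
        out = predict_map(gmlr, stack, None, truth.weights, truth.stations)
        np.testing.assert_allclose(out.filter_surface.values, 0.0, atol=1e-12)

    def test_matches_scalar_loop(self, scene):
        truth, stack, pf = scene
        model = pf.esfr
        out = predict_map(model, stack, pf.basis, pf.weights, truth.stations)
        mu_y, sd_y = model.standardization["__response__"]
        # recompute a handful of cells by scalar arithmetic outside the raster path
        for (i, j) in [(0, 0), (3, 17), (12, 5), (19, 19)]:
            x = stack[model.covariate_names[0]].x_centers[j]
            y = stack[model.covariate_names[0]].y_centers[i]
            acc = model.intercept
            for k, nm in enumerate(model.covariate_names):
                mu, sd = model.standardization[nm]
                acc += model.beta[k] * (stack[nm].values[i, j] - mu) / sd
            row = kernel_row(np.array([x, y]), truth.stations.xy, truth.weights.r)
            ext = nystrom_extend(pf.basis, truth.weights.C0, row, model.eigen_indices)
            acc += float(ext @ model.alpha)
            assert out.prediction.values[i, j] == pytest.approx(mu_y + sd_y * acc, rel=1e-10)
            assert out.filter_surface.values[i, j] == pytest.approx(float(ext @ model.alpha), rel=1e-8)

    def test_translation_equivariance(self, scene):
        truth, stack, pf = scene
        out1 = predict_map(pf.esfr, stack, pf.basis, pf.weights, truth.stations)
        shift = np.array([1000.0, -500.0])
        shifted_stations = StationSet(
            ids=truth.stations.ids,
            xy=truth.stations.xy + shift,
            values=truth.stations.values,
            covariates=truth.stations.covariates,
        )
        shifted_stack = {
            nm: RasterGrid(
                g.x0 + shift[0], g.y0 + shift[1], g.cell_size, g.ncols, g.nrows, values=g.values
            )
            for nm, g in stack.items()
        }
        pf2 = fit_pipeline(shifted_stations, prune=False)
        out2 = predict_map(pf2.esfr, shifted_stack, pf2.basis, pf2.weights, shifted_stations)
        np.testing.assert_allclose(out2.prediction.values, out1.prediction.values, atol=1e-6)

    def test_in_sample_identity_at_station_cells(self):
        # stations placed exactly at cell centers with rasters matching their
        # covariates: map prediction at those cells equals the fitted values
        cfg = SimulationConfig(seed=33, n_stations=30, sigma=1.0, region=(0, 0, 100, 100))
        from esfilter.synthetic_data import simulate_dataset

        truth = simulate_dataset(cfg)
        grid = RasterGrid.empty(0.0, 100.0, 2.0, 50, 50)
        # snap stations to distinct cell centers
        col = np.clip(((truth.stations.xy[:, 0]) // 2).astype(int), 0, 49)
        row = np.clip(((100.0 - truth.stations.xy[:, 1]) // 2).astype(int), 0, 49)
        _, keep = np.unique(np.column_stack([row, col]), axis=0, return_index=True)
        keep = np.sort(keep)
        row, col = row[keep], col[keep]
        snapped = np.column_stack([grid.x_centers[col], grid.y_centers[row]])
        st = StationSet(
            ids=truth.stations.ids[keep],
            xy=snapped,
            values=truth.stations.values[keep],
            covariates=truth.stations.covariates.iloc[keep].reset_index(drop=True),
        )
        pf = fit_pipeline(st, prune=False)
        stack = {}
        for nm in st.covariate_names:
            vals = np.zeros((50, 50))
            vals[row, col] = st.covariates[nm].to_numpy()
            stack[nm] = grid.like(vals)
        out = predict_map(pf.esfr, stack, pf.basis, pf.weights, st)
        np.testing.assert_allclose(
            out.prediction.values[row, col], pf.esfr.fitted, atol=1e-8
        )

    def test_misaligned_stack_rejected(self, scene):
        truth, stack, pf = scene
        bad = dict(stack)
        first = pf.esfr.covariate_names[0]
        g = bad[first]
        bad[first] = RasterGrid(g.x0 + 1.0, g.y0, g.cell_size, g.ncols, g.nrows, values=g.values)
        with pytest.raises(ValueError, match="aligned"):
            predict_map(pf.esfr, bad, pf.basis, pf.weights, truth.stations)

    def test_missing_layer_rejected(self, scene):
        truth, stack, pf = scene
        bad = {k: v for k, v in stack.items() if k != pf.esfr.covariate_names[0]}
        with pytest.raises(ValueError, match="missing"):
            predict_map(pf.esfr, bad, pf.basis, pf.weights, truth.stations)
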