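import numpy as np
import pytest

from lodgepoint.pointcloud import PointCloud
from lodgepoint.raster import (
    IDWConfig,
    REFERENCE_INTERP_ERRORS,
    evaluate_interpolation,
    idw,
    interpolation_benchmark_report,
    make_grid,
    read_ascii_grid,
    render_image,
    uniform_average,
    write_ascii_grid,
)


def brute_force_idw(samples, gx, gy, power=2.0):
    """Literal all-samples inverse-distance-weighted estimate (loop form)."""
    out = np.empty(len(gx))
    for i, (x, y) in enumerate(zip(gx, gy)):
        d = np.hypot(x - samples.x, y - samples.y)
        if (d == 0).any():
            out[i] = samples.z[d == 0].mean()
            continue
        w = d ** (-power)
        out[i] = (w * samples.z).sum() / w.sum()
    return out


class TestMakeGrid:
    def test_reference_plot_gives_780_by_380(self):
        grid = make_grid(7.8, 3.8, 0.01)
        assert (grid.rows, grid.cols) == (780, 380)

    @pytest.mark.parametrize("dx,dy,d,rows,cols", [
        (1.0, 1.0, 0.5, 2, 2),
        (1.0, 1.0, 0.3, 3, 3),   # round(3.33) = 3
        (0.75, 0.25, 0.5, 2, 1), # round half away from zero: 1.5 -> 2
    ])
    def test_rounding_convention(self, dx, dy, d, rows, cols):
        grid = make_grid(dx, dy, d)
        assert (grid.rows, grid.cols) == (rows, cols)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            make_grid(0.0, 1.0, 0.1)


class TestIDW:
    def test_single_sample_constant_field(self):
        samples = PointCloud(np.array([[0.5, 0.5, 0.7]]))
        raster = idw(samples, make_grid(1.0, 1.0, 0.25))
        assert np.allclose(raster.values, 0.7)

    def test_exact_hit_returns_sample_value(self):
        grid = make_grid(1.0, 1.0, 0.5)  # centres at 0.25/0.75
        samples = PointCloud(np.array([[0.25, 0.25, 2.0], [0.9, 0.9, 5.0]]))
        raster = idw(samples, grid)
        assert raster.values[0, 0] == pytest.approx(2.0)

    def test_equidistant_samples_average(self):
        grid = make_grid(1.0, 1.0, 1.0)  # single centre (0.5, 0.5)
        samples = PointCloud(np.array([[0.0, 0.5, 0.0], [1.0, 0.5, 1.0]]))
        raster = idw(samples, grid)
        assert raster.values[0, 0] == pytest.approx(0.5)

    def test_all_samples_mode_matches_brute_force(self, rng):
        samples = PointCloud(np.column_stack([
            rng.uniform(0, 2, 60), rng.uniform(0, 1, 60), rng.normal(1.0, 0.2, 60)
        ]))
        grid = make_grid(2.0, 1.0, 0.2)
        raster = idw(samples, grid, IDWConfig(k_neighbors=0))
        gx, gy = grid.cell_centers()
        np.testing.assert_allclose(
            raster.values.ravel(), brute_force_idw(samples, gx, gy), atol=1e-12
        )

    def test_k_limited_equals_all_samples_when_k_exceeds_m(self, rng):
        samples = PointCloud(rng.uniform(0, 1, (8, 3)))
        grid = make_grid(1.0, 1.0, 0.25)
        full = idw(samples, grid, IDWConfig(k_neighbors=0))
        limited = idw(samples, grid, IDWConfig(k_neighbors=50))
        np.testing.assert_allclose(limited.values, full.values, atol=1e-12)

    def test_convexity_bounds_output_by_sample_extremes(self, rng):
        samples = PointCloud(np.column_stack([
            rng.uniform(0, 1, 100), rng.uniform(0, 1, 100), rng.uniform(-3, 9, 100)
        ]))
        raster = idw(samples, make_grid(1.0, 1.0, 0.1), IDWConfig(k_neighbors=12))
        assert raster.values.min() >= samples.z.min() - 1e-12
        assert raster.values.max() <= samples.z.max() + 1e-12

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            idw(PointCloud(np.empty((0, 3))), make_grid(1, 1, 0.5))


class TestRenderImage:
    def test_constant_raster_single_colour(self):
        raster = idw(PointCloud(np.array([[0.5, 0.5, 0.6]])), make_grid(1, 1, 0.25))
        img = render_image(raster, 0.0, 1.2)
        assert img.shape == (4, 4, 3)
        assert len(np.unique(img.reshape(-1, 3), axis=0)) == 1

    def test_extremes_map_to_colormap_endpoints(self):
        import matplotlib

        samples = PointCloud(np.array([[0.25, 0.5, -5.0], [0.75, 0.5, 5.0]]))
        raster = idw(samples, make_grid(1.0, 1.0, 0.5), IDWConfig(k_neighbors=1))
        img = render_image(raster, 0.0, 1.0, "viridis")
        cmap = matplotlib.colormaps["viridis"]
        lo = (np.array(cmap(0.0)[:3]) * 255).astype(np.uint8)
        hi = (np.array(cmap(1.0)[:3]) * 255).astype(np.uint8)
        assert (img[0, 0] == lo).all() and (img[1, 1] == hi).all()

    def test_deterministic(self, rng):
        samples = PointCloud(rng.uniform(0, 1, (30, 3)))
        raster = idw(samples, make_grid(1, 1, 0.1))
        a = render_image(raster, 0, 1)
        b = render_image(raster, 0, 1)
        assert (a == b).all()

    def test_inverted_range_rejected(self):
        raster = idw(PointCloud(np.array([[0.5, 0.5, 0.6]])), make_grid(1, 1, 0.5))
        with pytest.raises(ValueError):
            render_image(raster, 1.0, 0.5)


class TestEvaluateInterpolation:
    def test_constant_surface_reconstructs_exactly(self, rng):
        xy = rng.uniform(0, 2, (100, 2))
        samples = PointCloud(np.column_stack([xy, np.full(100, 0.8)]))
        rep = evaluate_interpolation(samples, make_grid(2, 2, 0.1), seed=0)
        assert rep.mae == pytest.approx(0.0, abs=1e-9)
        assert rep.sd == pytest.approx(0.0, abs=1e-9)
        assert rep.median == pytest.approx(0.0, abs=1e-9)

    def test_known_residuals_give_closed_form_metrics(self, rng):
        # kept samples lie on the z=0 plane, so every held-out prediction is
        # exactly 0; held-out z of -/+1 mm forces residuals of +/-1 mm
        n, frac, seed = 40, 0.25, 5
        hold = np.random.default_rng(seed).permutation(n)[: int(n * frac)]
        z = np.zeros(n)
        z[hold] = np.where(np.arange(len(hold)) % 2 == 0, 1e-3, -1e-3)
        xy = rng.uniform(0, 1, (n, 2))
        samples = PointCloud(np.column_stack([xy, z]))
        rep = evaluate_interpolation(samples, make_grid(1, 1, 0.1),
                                     holdout_fraction=frac, seed=seed)
        assert rep.mae == pytest.approx(1.0, abs=1e-9)
        assert rep.sd == pytest.approx(1.0, abs=1e-9)
        assert rep.median == pytest.approx(1.0, abs=1e-9)

    def test_idw_beats_uniform_average_on_smooth_surface(self, rng):
        xy = rng.uniform(0, 4, (600, 2))
        z = 0.5 + 0.3 * np.sin(xy[:, 0]) * np.cos(xy[:, 1])
        samples = PointCloud(np.column_stack([xy, z]))
        grid = make_grid(4, 4, 0.2)
        rep_idw = evaluate_interpolation(samples, grid, seed=3, interpolator="idw")
        rep_uni = evaluate_interpolation(samples, grid, seed=3, interpolator="uniform")
        assert rep_idw.mae < rep_uni.mae

    def test_degenerate_holdout_rejected(self):
        samples = PointCloud(np.array([[0.0, 0.0, 1.0], [1.0, 1.0, 2.0]]))
        with pytest.raises(ValueError):
            evaluate_interpolation(samples, make_grid(1, 1, 0.5), holdout_fraction=0.01)


class TestAsciiGrid:
    def test_round_trip(self, tmp_path, rng):
        grid = make_grid(1.0, 2.0, 0.5, origin=(3.0, -1.0))
        values = rng.normal(size=(grid.rows, grid.cols))
        path = write_ascii_grid(values, grid, tmp_path / "g.asc")
        back, bgrid = read_ascii_grid(path)
        np.testing.assert_allclose(back, values, atol=1e-6)
        assert (bgrid.rows, bgrid.cols) == (grid.rows, grid.cols)
        assert bgrid.origin == grid.origin


class TestBenchmarkReport:
    def test_filling_stage_reductions_match_published_arithmetic(self):
        rep = interpolation_benchmark_report()
        lle = rep["local_linear_embedding"]["filling"]
        bhs = rep["biharmonic_spline"]["filling"]
        assert round(lle["mae"], 1) == 49.6
        assert round(bhs["mae"], 0) == 28
        assert round(lle["median"], 1) == 63.8
        assert round(lle["sd"], 1) == 41.5
        assert round(bhs["sd"], 1) == 12.6
        assert round(bhs["median"], 1) == 34.7

    def test_reference_errors_ordering(self):
        # IDW has the smallest error on every stage and metric
        for stage in ("filling", "maturity"):
            for metric in ("mae", "sd", "median"):
                idw_err = REFERENCE_INTERP_ERRORS["idw"][stage][metric]
                for other in ("local_linear_embedding", "biharmonic_spline"):
                    assert idw_err < REFERENCE_INTERP_ERRORS[other][stage][metric]

    def test_unimplemented_interpolators_are_explicit_stubs(self):
        from lodgepoint.raster import INTERPOLATORS

        with pytest.raises(NotImplementedError):
            INTERPOLATORS["local_linear_embedding"]()
        with pytest.raises(NotImplementedError):
            INTERPOLATORS["biharmonic_spline"]()
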