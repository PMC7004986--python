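"""Pathline layer: augmented velocity, seeds, integration, MDF clustering,
rasterization and per-mask summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from romtflow.grid import ImageGrid, ScalarField, VectorField
from romtflow.lagrangian import (
    Pathline,
    PathlineSet,
    augmented_velocity,
    cluster_and_filter,
    compute_streamlines,
    integrate_pathlines,
    mdf_distance,
    rasterize_pathlines,
    resample_pathline,
    select_start_points,
    summarize_by_mask,
    timeline_from_solutions,
    VelocityTimeline,
)
from romtflow.phantoms import analytic_field
from romtflow.preprocess import DensitySeries


def make_pathline(points, speed=1.0, start=(0, 0, 0)):
    points = np.asarray(points, dtype=float)
    return Pathline(points, np.full(len(points), speed), start)


class TestAugmentedVelocity:
    def test_zero_diffusivity_returns_velocity(self, rng, grid6):
        v = VectorField(grid6, rng.normal(size=(3, *grid6.dims)))
        mu = ScalarField(grid6, rng.uniform(0.5, 1.0, grid6.dims))
        out = augmented_velocity(v, mu, 0.0)
        assert np.array_equal(out.components, v.components)

    def test_constant_density_returns_velocity(self, rng, grid6):
        v = VectorField(grid6, rng.normal(size=(3, *grid6.dims)))
        mu = ScalarField(grid6, np.full(grid6.dims, 4.0))
        out = augmented_velocity(v, mu, 0.01)
        assert np.allclose(out.components, v.components)

    def test_gaussian_log_gradient_analytic(self):
        # mu ~ exp(-x^2/2s^2), v=0: v_aug_x = sigma2 * x / s^2
        grid = ImageGrid((41, 1, 1))
        x = np.arange(41, dtype=float) - 20.0
        s = 4.0
        mu = ScalarField(grid, np.exp(-(x**2) / (2 * s**2)).reshape(grid.dims))
        out = augmented_velocity(VectorField.zeros(grid), mu, 0.002, floor_fraction=1e-12)
        interior = slice(5, 36)  # away from floor and boundary stencils
        expected = 0.002 * x[interior] / s**2
        assert np.allclose(out.components[0, interior, 0, 0], expected, atol=1e-5)


class TestSelectStartPoints:
    def _series(self, stack):
        grid = ImageGrid(stack.shape[1:])
        return DensitySeries(
            frames=[ScalarField(grid, f) for f in stack],
            times=np.arange(len(stack), dtype=float),
            units="percent_baseline",
        )

    def test_constant_series_gives_empty_set(self):
        series = self._series(np.full((3, 4, 4, 4), 100.0))
        assert len(select_start_points(series)) == 0

    def test_threshold_boundary_cases(self):
        stack = np.full((2, 3, 3, 3), 100.0)
        stack[1, 0, 0, 0] = 115.0  # +15% -> selected
        stack[1, 1, 1, 1] = 110.0  # +10% -> excluded at 12%
        seeds = select_start_points(self._series(stack), threshold=0.12)
        assert [0, 0, 0] in seeds.tolist()
        assert [1, 1, 1] not in seeds.tolist()

    def test_requires_percent_units(self, grid6):
        series = DensitySeries(
            frames=[ScalarField(grid6, np.ones(grid6.dims))] * 2,
            times=np.array([0.0, 1.0]), units="raw",
        )
        with pytest.raises(ValueError, match="percent_baseline"):
            select_start_points(series)


class TestIntegration:
    def test_zero_field_is_fixed_point(self, grid6):
        tl = VelocityTimeline([VectorField.zeros(grid6)], np.array([1.0]))
        ps = integrate_pathlines(tl, np.array([[2, 3, 2]]), grid6, step_dt=0.25)
        pl = ps.pathlines[0]
        assert np.allclose(pl.points, pl.points[0])
        assert np.allclose(pl.speeds, 0.0)

    def test_constant_field_straight_segment(self):
        grid = ImageGrid((16, 8, 8))
        u = analytic_field(grid, "constant", value=[1.5, 0.0, 0.0])
        tl = VelocityTimeline([u, u], np.array([0.5, 0.5]))
        ps = integrate_pathlines(tl, np.array([[3, 4, 4]]), grid, step_dt=0.05)
        pl = ps.pathlines[0]
        assert pl.length == pytest.approx(1.5, rel=1e-9)  # |u| * T
        assert np.allclose(pl.speeds, 1.5)
        assert np.allclose(pl.points[-1] - pl.points[0], [1.5, 0, 0], atol=1e-9)

    def test_trajectory_truncated_at_domain_boundary(self):
        grid = ImageGrid((8, 8, 8))
        u = analytic_field(grid, "constant", value=[10.0, 0.0, 0.0])
        tl = VelocityTimeline([u], np.array([1.0]))
        ps = integrate_pathlines(tl, np.array([[4, 4, 4]]), grid, step_dt=0.05)
        pts = ps.pathlines[0].points
        assert pts[-1, 0] <= grid.dims[0] - 1 + 1e-9
        assert len(pts) < 21  # truncated before the full 20 steps

    def test_frozen_rotation_closes_on_itself(self):
        grid = ImageGrid((16, 16, 16))
        v = analytic_field(grid, "rotation", omega=2 * np.pi)
        seed = np.array([[11.5, 7.5, 7.5]])
        ps = compute_streamlines(v, seed, step_dt=1 / 128, total_time=1.0)
        pl = ps.pathlines[0]
        err = np.linalg.norm(pl.points[-1] - pl.points[0])
        assert err < 1e-3

    def test_seeds_outside_domain_rejected(self, grid6):
        tl = VelocityTimeline([VectorField.zeros(grid6)], np.array([1.0]))
        with pytest.raises(ValueError, match="inside the grid"):
            integrate_pathlines(tl, np.array([[9, 0, 0]]), grid6)

    def test_speed_equals_field_magnitude_at_samples(self):
        grid = ImageGrid((12, 12, 12))
        v = analytic_field(grid, "radial", rate=0.2)
        ps = compute_streamlines(v, np.array([[8, 6, 6]]), step_dt=0.1, total_time=0.5)
        pl = ps.pathlines[0]
        mags = []
        for p in pl.points:
            idx = grid.world_to_voxel(p)
            rel = idx - (np.array(grid.dims) - 1) / 2.0
            mags.append(0.2 * np.linalg.norm(rel))
        assert np.allclose(pl.speeds, mags, rtol=1e-6)


class TestMdfAndClustering:
    def test_identical_curves_zero_distance(self):
        a = np.linspace([0, 0, 0], [5, 0, 0], 12)
        assert mdf_distance(a, a.copy()) == 0.0

    def test_parallel_offset_equals_offset_norm(self):
        a = np.linspace([0, 0, 0], [5, 0, 0], 12)
        d = np.array([0.0, 2.0, 1.0])
        assert mdf_distance(a, a + d) == pytest.approx(np.linalg.norm(d))

    def test_flip_invariance(self, rng):
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        assert mdf_distance(a, b) == pytest.approx(mdf_distance(a, b[::-1]))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_mdf_metric_properties(self, seed):
        """Symmetry, nonnegativity, and zero on identical curves."""
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=(2, 12, 3))
        assert mdf_distance(a, b) >= 0
        assert mdf_distance(a, b) == pytest.approx(mdf_distance(b, a))
        assert mdf_distance(a, a) == 0.0

    def test_two_identical_pathlines_one_cluster(self, grid6):
        pts = np.linspace([0, 0, 0], [4, 0, 0], 8)
        ps = PathlineSet([make_pathline(pts), make_pathline(pts)], grid6)
        out = cluster_and_filter(ps, cluster_threshold=1.0, min_cluster_size=1)
        assert len(out) == 2
        assert out.pathlines[0].cluster_id == out.pathlines[1].cluster_id

    def test_offset_pair_split_by_threshold(self, grid6):
        pts = np.linspace([0, 0, 0], [4, 0, 0], 8)
        far = pts + np.array([0.0, 3.0, 0.0])
        ps = PathlineSet([make_pathline(pts), make_pathline(far)], grid6)
        joined = cluster_and_filter(ps, cluster_threshold=3.5, min_cluster_size=1)
        split = cluster_and_filter(ps, cluster_threshold=2.5, min_cluster_size=1)
        assert joined.pathlines[0].cluster_id == joined.pathlines[1].cluster_id
        assert split.pathlines[0].cluster_id != split.pathlines[1].cluster_id

    def test_singleton_cluster_removed(self, grid6):
        pts = np.linspace([0, 0, 0], [4, 0, 0], 8)
        lone = pts + np.array([0.0, 4.0, 0.0])
        ps = PathlineSet(
            [make_pathline(pts), make_pathline(pts), make_pathline(lone)], grid6
        )
        out = cluster_and_filter(ps, cluster_threshold=1.0, min_cluster_size=2)
        assert len(out) == 2

    def test_resample_preserves_endpoints(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 2, 0]], dtype=float)
        rs = resample_pathline(pts, 12)
        assert np.allclose(rs[0], pts[0])
        assert np.allclose(rs[-1], pts[-1])


class TestRasterizeAndSummaries:
    def test_empty_set_gives_zero_field(self, grid6):
        out = rasterize_pathlines(PathlineSet([], grid6), "binary")
        assert np.all(out.values == 0)

    def test_axis_aligned_centers_binary_volume(self):
        grid = ImageGrid((8, 8, 8))
        pts = np.array([[2.0, 3.0, 3.0], [3.0, 3.0, 3.0], [4.0, 3.0, 3.0]])
        ps = PathlineSet([make_pathline(pts)], grid)
        out = rasterize_pathlines(ps, "binary")
        assert out.values.sum() == 3

    def test_constant_speed_map_uniform(self):
        grid = ImageGrid((8, 8, 8))
        pts = np.array([[2.0, 3.0, 3.0], [3.5, 3.0, 3.0], [5.0, 3.0, 3.0]])
        ps = PathlineSet([make_pathline(pts, speed=0.7)], grid)
        speed = rasterize_pathlines(ps, "speed")
        nz = speed.values[speed.values > 0]
        assert np.allclose(nz, 0.7)

    def test_binary_volume_additive_for_disjoint_sets(self, grid6):
        a = PathlineSet([make_pathline([[1.0, 1.0, 1.0]])], grid6)
        b = PathlineSet([make_pathline([[4.0, 4.0, 4.0]])], grid6)
        both = PathlineSet(a.pathlines + b.pathlines, grid6)
        va = rasterize_pathlines(a, "binary").values.sum()
        vb = rasterize_pathlines(b, "binary").values.sum()
        vab = rasterize_pathlines(both, "binary").values.sum()
        assert vab == va + vb

    def test_summaries_partition_and_empty_mask(self, grid6):
        pts = np.array([[1.0, 1.0, 1.0], [4.0, 4.0, 4.0]])
        ps = PathlineSet([make_pathline(pts, speed=0.5)], grid6)
        binary = rasterize_pathlines(ps, "binary")
        speed = rasterize_pathlines(ps, "speed")
        half = np.zeros(grid6.dims, bool)
        half[:3] = True
        table = summarize_by_mask(
            binary, speed,
            {"lower": half, "upper": ~half, "whole": np.ones(grid6.dims, bool),
             "empty_corner": np.zeros(grid6.dims, bool)},
        ).set_index("mask")
        total = binary.values.sum()
        assert table.loc["whole", "pathline_volume_voxels"] == total
        assert (
            table.loc["lower", "pathline_volume_voxels"]
            + table.loc["upper", "pathline_volume_voxels"]
            == total
        )
        assert table.loc["empty_corner", "pathline_volume_voxels"] == 0
        assert np.isnan(table.loc["empty_corner", "mean_speed"])
        assert table.loc["whole", "mean_speed"] == pytest.approx(0.5)
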