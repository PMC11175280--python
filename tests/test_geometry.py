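import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ablapath import (
    EmptyMaskError,
    GeometryError,
    NoCrossingError,
    Segment,
    VoxelGrid,
    capsule_angle,
    capsule_crossing,
    distance_transform,
    min_distance_along_segment,
    sample_segment,
    segment_intersects,
    surface_normal,
    traverse_voxels,
)
from _oracles import nearest_voxel_distance_bruteforce, sampled_collision


class TestSampleSegment:
    def test_equally_spaced_count(self):
        seg = Segment((0, 0, 0), (10, 0, 0))
        pts = sample_segment(seg, 1.0)
        assert len(pts) == 11
        np.testing.assert_allclose(np.diff(pts[:, 0]), 1.0)

    def test_step_larger_than_length_gives_endpoints(self):
        seg = Segment((1, 2, 3), (2, 2, 3))
        pts = sample_segment(seg, 5.0)
        assert len(pts) == 2
        np.testing.assert_allclose(pts[0], (1, 2, 3))
        np.testing.assert_allclose(pts[-1], (2, 2, 3))

    @given(st.floats(0.05, 5.0), st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_collinear_and_bounded_gaps(self, step, seed):
        rng = np.random.default_rng(seed)
        p0, p1 = rng.uniform(-50, 50, size=(2, 3))
        if np.linalg.norm(p1 - p0) < 1e-6:
            return
        seg = Segment(tuple(p0), tuple(p1))
        pts = sample_segment(seg, step)
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert gaps.max() <= step + 1e-9
        # collinearity: cross product of offsets with the direction vanishes
        cross = np.cross(pts - seg.a, seg.direction)
        assert np.abs(cross).max() < 1e-9

    def test_zero_length_rejected(self):
        with pytest.raises(GeometryError):
            Segment((1, 1, 1), (1, 1, 1))


class TestSegmentIntersects:
    def test_through_solid_cube(self, unit_grid):
        mask = np.zeros(unit_grid.shape, dtype=bool)
        mask[10:20, 10:20, 10:20] = True
        seg = Segment((0, 15, 15), (31, 15, 15))
        assert segment_intersects(mask, unit_grid, seg)

    def test_outside_bounding_box(self, unit_grid):
        mask = np.zeros(unit_grid.shape, dtype=bool)
        mask[10:20, 10:20, 10:20] = True
        seg = Segment((0, 25, 25), (31, 25, 25))
        assert not segment_intersects(mask, unit_grid, seg)

    def test_entirely_outside_grid_is_nonintersecting(self, unit_grid):
        mask = np.ones(unit_grid.shape, dtype=bool)
        seg = Segment((100, 100, 100), (120, 120, 120))
        assert not segment_intersects(mask, unit_grid, seg)

    def test_exact_traversal_vs_dense_sampling_oracle(self, unit_grid):
        """Verdicts agree with a step/10 sampling oracle except for grazing
        hits the sampler can miss (never the other way round)."""
        rng = np.random.default_rng(11)
        mask = np.zeros(unit_grid.shape, dtype=bool)
        mask[12:18, 12:18, 12:18] = True
        disagreements = 0
        for _ in range(200):
            p0 = rng.uniform(0, 31, size=3)
            p1 = rng.uniform(0, 31, size=3)
            if np.linalg.norm(p1 - p0) < 1.0:
                continue
            seg = Segment(tuple(p0), tuple(p1))
            exact = segment_intersects(mask, unit_grid, seg)
            dense = sampled_collision(mask, unit_grid, seg, step=0.05)
            if exact != dense:
                # exact traversal may only be MORE sensitive than sampling
                assert exact and not dense
                disagreements += 1
        assert disagreements <= 10

    def test_traversal_covers_sampled_voxels(self, unit_grid):
        """Every voxel hit by dense sampling is also traversed."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            p0 = rng.uniform(-5, 36, size=3)
            p1 = rng.uniform(-5, 36, size=3)
            if np.linalg.norm(p1 - p0) < 1.0:
                continue
            seg = Segment(tuple(p0), tuple(p1))
            traversed = set(traverse_voxels(unit_grid, seg))
            pts = sample_segment(seg, 0.05)
            idx = np.rint(pts).astype(int)
            inb = np.all((idx >= 0) & (idx < 32), axis=1)
            # nearest-voxel rounding can land in an adjacent cell exactly at
            # a .5 boundary; tolerate only exact-boundary cases
            for v in map(tuple, idx[inb]):
                if v not in traversed:
                    assert any(abs(c - round(c)) < 1e-6 for c in pts[inb][0])


class TestDistanceTransform:
    def test_3_4_5_triangle(self, unit_grid):
        mask = np.zeros(unit_grid.shape, dtype=bool)
        mask[5, 5, 5] = True
        field = distance_transform(mask, unit_grid)
        assert field.values[8, 9, 5] == pytest.approx(5.0)
        assert field.values[5, 5, 5] == 0.0

    def test_anisotropic_plane_offset(self):
        grid = VoxelGrid(shape=(8, 8, 8), spacing=(1.0, 1.0, 2.0))
        mask = np.zeros(grid.shape, dtype=bool)
        mask[:, :, 0] = True
        field = distance_transform(mask, grid)
        assert field.values[3, 3, 2] == pytest.approx(4.0)

    def test_matches_bruteforce_on_small_volumes(self):
        rng = np.random.default_rng(4)
        grid = VoxelGrid(shape=(12, 13, 14), spacing=(0.8, 1.1, 2.3))
        mask = rng.random(grid.shape) < 0.03
        mask[3, 3, 3] = True
        field = distance_transform(mask, grid)
        for index in [(0, 0, 0), (11, 12, 13), (6, 6, 6), (2, 9, 4)]:
            expected = nearest_voxel_distance_bruteforce(mask, grid, index)
            assert field.values[index] == pytest.approx(expected, abs=1e-9)

    def test_empty_mask_instructs_caller(self, unit_grid):
        with pytest.raises(EmptyMaskError, match="infinit"):
            distance_transform(np.zeros(unit_grid.shape, dtype=bool), unit_grid)


class TestMinDistanceAlongSegment:
    def test_parallel_to_marked_plane(self, unit_grid):
        mask = np.zeros(unit_grid.shape, dtype=bool)
        mask[:, :, 0] = True
        field = distance_transform(mask, unit_grid)
        seg = Segment((2, 2, 7), (28, 28, 7))
        assert min_distance_along_segment(field, seg, step=0.5) == pytest.approx(7.0, abs=0.05)

    def test_touching_structure_is_zero(self, unit_grid):
        mask = np.zeros(unit_grid.shape, dtype=bool)
        mask[15, 15, 15] = True
        field = distance_transform(mask, unit_grid)
        seg = Segment((15, 15, 0), (15, 15, 30))
        assert min_distance_along_segment(field, seg, step=0.25) == pytest.approx(0.0, abs=1e-6)

    def test_refinement_within_lipschitz_bound(self, unit_grid):
        """Coarse minimum exceeds the dense minimum by at most one step
        (the distance field is 1-Lipschitz in world coordinates)."""
        rng = np.random.default_rng(9)
        mask = np.zeros(unit_grid.shape, dtype=bool)
        mask[10:14, 18:22, 8:12] = True
        field = distance_transform(mask, unit_grid)
        for _ in range(30):
            p0, p1 = rng.uniform(1, 30, size=(2, 3))
            if np.linalg.norm(p1 - p0) < 2:
                continue
            seg = Segment(tuple(p0), tuple(p1))
            coarse = min_distance_along_segment(field, seg, step=2.0)
            dense = min_distance_along_segment(field, seg, step=0.2)
            # both bracket the continuum minimum to within half their step
            assert dense <= coarse + 0.1 + 1e-9
            assert coarse - dense <= 1.0 + 1e-9


class TestCapsuleCrossing:
    def test_halfspace_plane(self, unit_grid):
        # liver = voxels with z >= 11, membership boundary at z = 10.5
        mask = np.zeros(unit_grid.shape, dtype=bool)
        mask[:, :, 11:] = True
        seg = Segment((15, 15, 0), (15, 15, 30))
        crossing = capsule_crossing(mask, unit_grid, seg)
        assert crossing[2] == pytest.approx(10.5, abs=0.1)

    def test_inside_liver_is_degenerate(self, unit_grid):
        mask = np.ones(unit_grid.shape, dtype=bool)
        seg = Segment((10, 10, 10), (20, 20, 20))
        crossing = capsule_crossing(mask, unit_grid, seg)
        np.testing.assert_allclose(crossing, (10, 10, 10))

    def test_never_entering_raises(self, unit_grid):
        mask = np.zeros(unit_grid.shape, dtype=bool)
        mask[0:2, 0:2, 0:2] = True
        seg = Segment((30, 30, 30), (20, 30, 30))
        with pytest.raises(NoCrossingError):
            capsule_crossing(mask, unit_grid, seg)

    def test_sphere_radial_ray_analytic(self):
        """Axis-aligned radial ray into a rasterized sphere of half-integer
        radius crosses exactly at the analytic radius."""
        grid = VoxelGrid(shape=(41, 41, 41), spacing=(1, 1, 1), origin=(-20, -20, -20))
        xs = np.arange(41) - 20.0
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        radius = 10.5
        mask = X**2 + Y**2 + Z**2 <= radius**2
        seg = Segment((19, 0, 0), (0, 0, 0))
        crossing = capsule_crossing(mask, grid, seg)
        assert np.linalg.norm(crossing) == pytest.approx(radius, abs=0.1)


class TestSurfaceNormalAndAngle:
    def _slab(self, grid):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[:, :, 16:] = True
        return mask

    def test_flat_slab_normal(self, unit_grid):
        mask = self._slab(unit_grid)
        n = surface_normal(mask, unit_grid, (15.0, 15.0, 15.5), sigma=2.0)
        assert np.linalg.norm(n) == pytest.approx(1.0, abs=1e-9)
        angle = np.degrees(np.arccos(np.clip(np.dot(n, (0, 0, -1)), -1, 1)))
        assert angle < 2.0  # outward = toward smaller z

    def test_sphere_normals_radial(self):
        grid = VoxelGrid(shape=(41, 41, 41), spacing=(1, 1, 1), origin=(-20, -20, -20))
        xs = np.arange(41) - 20.0
        X, Y, Z = np.meshgrid(xs, xs, xs, indexing="ij")
        mask = X**2 + Y**2 + Z**2 <= 12.0**2
        for direction in [(1, 0, 0), (0, 1, 0), (0, 0, 1),
                          (1, 1, 1), (1, -2, 0.5)]:
            d = np.asarray(direction, float)
            d /= np.linalg.norm(d)
            point = 12.0 * d
            n = surface_normal(mask, grid, point, sigma=2.0)
            misalign = np.degrees(np.arccos(np.clip(np.dot(n, d), -1, 1)))
            assert misalign < 3.0

    def test_perpendicular_insertion_is_90deg(self, unit_grid):
        mask = self._slab(unit_grid)
        seg = Segment((15, 15, 0), (15, 15, 30))
        assert capsule_angle(mask, unit_grid, seg, sigma=2.0) == pytest.approx(90.0, abs=2.0)

    def test_45deg_insertion(self, unit_grid):
        mask = self._slab(unit_grid)
        seg = Segment((5, 15, 5.5), (25, 15, 25.5))  # direction (1,0,1)/sqrt2
        assert capsule_angle(mask, unit_grid, seg, sigma=2.0) == pytest.approx(45.0, abs=3.0)

    def test_angle_invariant_to_normal_sign(self):
        from ablapath.geometry import angle_from_normal

        d = np.array([0.0, 0.0, 1.0])
        n = np.array([0.0, 0.6, 0.8])
        assert angle_from_normal(d, n) == pytest.approx(angle_from_normal(d, -n))
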