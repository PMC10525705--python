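"""Contour geometry: centroids, sector grids, resampling, mask conversion."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lssdmap import (
    ContourError,
    SliceContour,
    StructureContours,
    build_sector_grid,
    make_tube,
    mask_to_polygons,
    polygons_to_mask,
    resample_ring,
    sector_membership,
    slice_centroid,
)
from lssdmap.geometry import boundary_points, sector_indices

UNIT_SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def circle_ring(r, center=(0.0, 0.0), n=128):
    t = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


class TestSliceCentroid:
    @pytest.mark.parametrize(
        "rings, expected",
        [
            ((UNIT_SQUARE,), (0.5, 0.5)),
            ((circle_ring(50, (10, -20)),), (10.0, -20.0)),
            # two disjoint equal-area squares centred at (0,0) and (4,0)
            ((UNIT_SQUARE - 0.5, UNIT_SQUARE + [3.5, -0.5]), (2.0, 0.0)),
        ],
    )
    def test_known_centroids(self, rings, expected):
        sc = SliceContour(z=0.0, rings=rings)
        assert slice_centroid(sc) == pytest.approx(expected, abs=1e-6)

    def test_degenerate_ring_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ContourError):
            SliceContour(z=0.0, rings=(line,))

    @given(
        dx=st.floats(-200, 200, allow_nan=False),
        dy=st.floats(-200, 200, allow_nan=False),
    )
    def test_translation_equivariance(self, dx, dy):
        sc = SliceContour(z=0.0, rings=(circle_ring(30, (2, 7), n=64), UNIT_SQUARE + 60))
        cx, cy = slice_centroid(sc)
        tx, ty = slice_centroid(sc.translated(dx, dy))
        assert tx == pytest.approx(cx + dx, abs=1e-8)
        assert ty == pytest.approx(cy + dy, abs=1e-8)


class TestSectorGrid:
    def test_n_sectors_from_width(self, circle_tube):
        grid = build_sector_grid(circle_tube, 10.0)
        assert grid.n_sectors == 36
        assert len(grid.origin_per_slice) == circle_tube.n_slices

    def test_quadrant_partition(self, circle_tube):
        grid = build_sector_grid(circle_tube, 90.0)
        assert grid.n_sectors == 4
        np.testing.assert_allclose(grid.sector_start_angles(), [0, 90, 180, 270])

    def test_non_divisor_width_rejected(self, circle_tube):
        with pytest.raises(ValueError, match="valid widths"):
            build_sector_grid(circle_tube, 7.0)

    def test_anatomical_axes(self, circle_tube):
        # HFS axes: +x patient-left, -y anterior, -x right, +y posterior
        grid = build_sector_grid(circle_tube, 90.0)
        origin = (0.0, 0.0)
        assert sector_membership((10.0, 0.0), origin, grid) == 0  # left
        assert sector_membership((0.0, -10.0), origin, grid) == 1  # anterior
        assert sector_membership((-10.0, 0.0), origin, grid) == 2  # right
        assert sector_membership((0.0, 10.0), origin, grid) == 3  # posterior

    def test_membership_by_floor_of_angle(self, circle_tube):
        grid = build_sector_grid(circle_tube, 10.0)
        p = (math.cos(math.radians(45)), -math.sin(math.radians(45)))
        assert sector_membership(p, (0.0, 0.0), grid) == 4

    def test_origin_point_warns_to_sector_zero(self, circle_tube, caplog):
        grid = build_sector_grid(circle_tube, 10.0)
        with caplog.at_level("WARNING"):
            assert sector_membership((3.0, 4.0), (3.0, 4.0), grid) == 0
        assert "origin" in caplog.text

    @given(seed=st.integers(0, 2**16))
    def test_membership_exhaustive_and_exclusive(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(0, 30, size=(200, 2))
        idx = sector_indices(pts, (0.0, 0.0), 10.0)
        assert idx.min() >= 0 and idx.max() < 36
        counts = np.bincount(idx, minlength=36)
        assert counts.sum() == len(pts)


class TestResampleRing:
    def test_square_densified_on_boundary(self):
        out = resample_ring(UNIT_SQUARE * 10, max_spacing=1.0)
        assert len(out) - 1 >= 40
        # every point on the square's boundary
        on_edge = (np.isclose(out[:, 0] % 10, 0) | np.isclose(out[:, 1] % 10, 0))
        assert on_edge.all()
        np.testing.assert_allclose(out[0], out[-1])
        steps = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert steps.max() <= 1.0 + 1e-12

    def test_dense_ring_unchanged_up_to_closure(self):
        ring = circle_ring(50, n=4096)  # spacing ~0.077 mm
        out = resample_ring(ring, max_spacing=0.5)
        np.testing.assert_array_equal(out[:-1], ring)

    def test_dense_circle_stays_on_radius(self):
        ring = circle_ring(50, n=4096)
        out = resample_ring(ring, max_spacing=0.5)
        assert len(out) - 1 >= 628  # 2*pi*50 / 0.5
        radii = np.hypot(out[:, 0], out[:, 1])
        np.testing.assert_allclose(radii, 50.0, atol=1e-9)

    def test_input_vertices_preserved(self):
        out = resample_ring(UNIT_SQUARE, max_spacing=0.3)
        for v in UNIT_SQUARE:
            assert np.any(np.all(np.isclose(out, v), axis=1))


class TestStructureInvariants:
    def test_z_must_increase(self):
        sq = SliceContour(z=0.0, rings=(UNIT_SQUARE,))
        sq2 = SliceContour(z=0.0, rings=(UNIT_SQUARE,))
        with pytest.raises(ContourError, match="increasing"):
            StructureContours("x", (sq, sq2), slice_spacing=1.0)

    def test_gap_must_match_spacing(self):
        slices = tuple(SliceContour(z=z, rings=(UNIT_SQUARE,)) for z in (0.0, 1.7))
        with pytest.raises(ContourError, match="spacing"):
            StructureContours("x", slices, slice_spacing=1.0)

    def test_missing_slice_gap_allowed(self):
        slices = tuple(SliceContour(z=z, rings=(UNIT_SQUARE,)) for z in (0.0, 1.0, 3.0))
        s = StructureContours("x", slices, slice_spacing=1.0)
        assert s.n_slices == 3


class TestMaskConversion:
    def test_circle_mask_area(self):
        tube = make_tube("circle", radii=50.0, z_range=(0.0, 0.0), slice_spacing=3.0)
        mask = polygons_to_mask(tube, (0.5, 0.5, 3.0))
        area = mask.foreground_count * 0.25
        assert area == pytest.approx(math.pi * 50**2, rel=0.01)

    def test_empty_structure_all_zero_with_warning(self):
        empty = StructureContours("x", (), slice_spacing=3.0)
        with pytest.warns(UserWarning, match="empty"):
            mask = polygons_to_mask(empty, (1.0, 1.0, 3.0), origin=(0, 0, 0),
                                    shape=(2, 8, 8))
        assert mask.foreground_count == 0

    @pytest.mark.parametrize("shape,radii", [("circle", 50.0), ("ellipse", (40.0, 25.0))])
    def test_round_trip_preserves_area(self, shape, radii):
        tube = make_tube(shape, radii=radii, z_range=(0.0, 6.0), slice_spacing=3.0)
        spacing = (0.5, 0.5, 3.0)
        back = mask_to_polygons(polygons_to_mask(tube, spacing))
        for s_in, s_out in zip(tube.slices, back.slices):
            perimeter = s_in.polygon.length
            tol = perimeter * max(spacing[:2])
            assert abs(s_in.area - s_out.area) <= tol
            assert s_out.z == pytest.approx(s_in.z)

    def test_rectangle_round_trip(self):
        rect = np.array([[0.0, 0.0], [40.0, 0.0], [40.0, 20.0], [0.0, 20.0]])
        s = StructureContours("r", (SliceContour(z=0.0, rings=(rect,)),), 3.0)
        back = mask_to_polygons(polygons_to_mask(s, (0.5, 0.5, 3.0)))
        assert abs(back.slices[0].area - 800.0) <= 120.0 * 0.5

    def test_boundary_point_counts_partition(self, ellipse_tube):
        sc = ellipse_tube.slices[0]
        pts = boundary_points(sc, 0.25)
        idx = sector_indices(pts, slice_centroid(sc), 10.0)
        assert np.bincount(idx, minlength=36).sum() == len(pts)
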