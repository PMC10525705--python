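"""Sector signed-distance metric: symmetric mean distance, P/Q sign, map assembly."""

import math

import numpy as np
import pytest

from lssdmap import (
    ContourError,
    compute_lssd_map,
    make_tube,
    perturb,
    radial_dilate,
    sector_mean_distance,
    sector_overlap_ratios,
    sign_distance,
)
from lssdmap.bruteforce import lssd_map_bruteforce
from lssdmap.metric import (
    STATUS_DEFINED,
    STATUS_EMPTY_REFERENCE,
    STATUS_EMPTY_TRAINEE,
    STATUS_REFERENCE_MISSING_SLICE,
    STATUS_TRAINEE_MISSING_SLICE,
)


def arc_points(r, a0_deg, a1_deg, step_mm):
    n = max(2, int(math.ceil(math.radians(a1_deg - a0_deg) * r / step_mm)))
    t = np.radians(np.linspace(a0_deg, a1_deg, n))
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


class TestSectorMeanDistance:
    def test_identical_sets_zero(self):
        pts = arc_points(50, 0, 10, 0.25)
        assert sector_mean_distance(pts, pts) == 0.0

    def test_single_pair(self):
        assert sector_mean_distance(np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]])) == 5.0

    def test_concentric_arcs_radial_offset(self):
        ref = arc_points(50, 40, 50, 0.1)
        tr = arc_points(40, 40, 50, 0.1)
        assert sector_mean_distance(ref, tr) == pytest.approx(10.0, abs=0.05)

    def test_empty_set_rejected(self):
        with pytest.raises(ContourError):
            sector_mean_distance(np.empty((0, 2)), np.array([[0.0, 0.0]]))


class TestOverlapRatiosAndSign:
    def test_identical_regions(self):
        assert sector_overlap_ratios(4.0, 4.0, 4.0) == (1.0, 1.0)

    def test_trainee_disc_inside_reference(self):
        # concentric discs r=40 inside r=50; any full sector of half-angle th:
        # areas are (th/2) r^2, intersection is the trainee sector
        th = math.radians(10.0)
        p, q = sector_overlap_ratios(0.5 * th * 50**2, 0.5 * th * 40**2, 0.5 * th * 40**2)
        assert p == pytest.approx(0.64)
        assert q == 1.0
        assert sign_distance(10.0, p, q) == -10.0

    def test_trainee_disc_outside_reference(self):
        th = math.radians(10.0)
        p, q = sector_overlap_ratios(0.5 * th * 50**2, 0.5 * th * 60**2, 0.5 * th * 50**2)
        assert p == 1.0
        assert q == pytest.approx(25 / 36)
        assert sign_distance(10.0, p, q) == 10.0

    def test_tie_is_positive(self):
        assert sign_distance(2.5, 0.7, 0.7) == 2.5

    def test_zero_area_rejected(self):
        with pytest.raises(ContourError):
            sector_overlap_ratios(0.0, 1.0, 0.0)


class TestComputeMap:
    def test_zero_law(self, ellipse_tube):
        m = compute_lssd_map(ellipse_tube, ellipse_tube, 10.0)
        assert m.valid.all()
        np.testing.assert_array_equal(m.values, 0.0)
        assert (m.status == STATUS_DEFINED).all()

    def test_concentric_shrink_is_minus_five(self, circle_tube):
        trainee = make_tube("circle", radii=45.0, z_range=(0.0, 27.0), slice_spacing=3.0)
        m = compute_lssd_map(trainee, circle_tube, 10.0)
        assert m.values.shape == (10, 36)
        assert m.valid.all()
        np.testing.assert_allclose(m.values, -5.0, atol=0.1)

    def test_shift_sign_pattern(self, circle_tube):
        trainee = circle_tube.translated(8.0, 0.0)
        m = compute_lssd_map(trainee, circle_tube, 10.0)
        centers = m.sector_start_angles() + 5.0
        shift_side = (centers < 45) | (centers > 315)
        far_side = (centers > 135) & (centers < 225)
        assert (m.values[:, shift_side] > 0).all()
        assert (m.values[:, far_side] < 0).all()
        # sectors straddling 90 and 270 degrees see little radial change
        orth = np.isin(m.sector_start_angles(), [80, 90, 260, 270])
        assert (np.abs(m.values[:, orth]) < 4.0).all()

    def test_swap_antisymmetry_common_centroid(self):
        a = make_tube("ellipse", center=(5, -3), radii=(40, 25), z_range=(0, 3),
                      slice_spacing=3.0, phase_deg=3.7)
        b = make_tube("circle", center=(5, -3), radii=33.0, z_range=(0, 3),
                      slice_spacing=3.0, phase_deg=3.7)
        m_ab = compute_lssd_map(a, b, 10.0)
        m_ba = compute_lssd_map(b, a, 10.0)
        np.testing.assert_array_equal(m_ab.valid, m_ba.valid)
        # |d| preserved, sign flipped wherever P != Q (P == Q nowhere here)
        np.testing.assert_allclose(m_ab.values[m_ab.valid], -m_ba.values[m_ba.valid],
                                   atol=1e-12)

    @pytest.mark.parametrize("delta", [1.0, 2.0, 4.0])
    def test_dilation_positive(self, ellipse_tube, delta):
        trainee = radial_dilate(ellipse_tube, delta)
        m = compute_lssd_map(trainee, ellipse_tube, 10.0)
        assert (m.values[m.valid] > 0).all()

    def test_dilation_monotone(self, ellipse_tube):
        prev = None
        for delta in (1.0, 2.0, 4.0):
            m = compute_lssd_map(radial_dilate(ellipse_tube, delta), ellipse_tube, 10.0)
            vals = m.values[m.valid]
            if prev is not None:
                assert (vals > prev).all()
            prev = vals

    def test_values_stored_unclipped(self, circle_tube):
        trainee = make_tube("circle", radii=30.0, z_range=(0.0, 27.0), slice_spacing=3.0)
        m = compute_lssd_map(trainee, circle_tube, 10.0)
        assert np.abs(m.values[m.valid]).max() > 3.0  # no +/-3 mm clamp in the data

    def test_empty_structure_rejected(self, circle_tube):
        from lssdmap import StructureContours

        empty = StructureContours("x", (), slice_spacing=3.0)
        with pytest.raises(ContourError):
            compute_lssd_map(empty, circle_tube, 10.0)

    def test_interior_z_gap_names_slices(self, circle_tube):
        # trainee missing an interior slice: not a superior/inferior overshoot,
        # so the grids genuinely disagree and the offending z is reported
        from lssdmap import StructureContours

        gappy = StructureContours(
            "Heart",
            tuple(s for s in circle_tube.slices if s.z != 12.0),
            slice_spacing=3.0,
        )
        with pytest.raises(ContourError, match="12"):
            compute_lssd_map(gappy, circle_tube, 10.0)

    def test_extent_mismatch_forced_rows(self):
        ref = make_tube("circle", radii=50.0, z_range=(0.0, 27.0), slice_spacing=3.0)
        trainee = make_tube("circle", radii=50.0, z_range=(0.0, 21.0), slice_spacing=3.0)
        m = compute_lssd_map(trainee, ref, 10.0)
        assert m.values.shape == (10, 36)
        # reference extends 1 and 2 slices beyond the trainee superiorly
        assert (m.status[8] == STATUS_TRAINEE_MISSING_SLICE).all()
        np.testing.assert_allclose(m.values[8], -3.0)
        np.testing.assert_allclose(m.values[9], -6.0)
        # and the mirrored case forces positive rows
        m2 = compute_lssd_map(ref, trainee, 10.0)
        assert (m2.status[9] == STATUS_REFERENCE_MISSING_SLICE).all()
        np.testing.assert_allclose(m2.values[9], 6.0)

    def test_sector_without_trainee_region_forced_negative(self):
        # trainee = small disc offset patient-right: wedges near 0 deg (left)
        # contain reference area but no trainee area at all
        ref = make_tube("circle", radii=50.0, z_range=(0.0, 0.0), slice_spacing=3.0)
        trainee = make_tube("circle", center=(-35.0, 0.0), radii=10.0,
                            z_range=(0.0, 0.0), slice_spacing=3.0)
        m = compute_lssd_map(trainee, ref, 10.0)
        k0 = 0  # sector [0, 10): patient-left of the reference centroid
        assert m.status[0, k0] == STATUS_EMPTY_TRAINEE
        assert m.values[0, k0] < 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_production_matches_bruteforce(self, seed):
        base = make_tube("ellipse", center=(4.0, -2.0), radii=(40.0, 25.0),
                         z_range=(0.0, 3.0), slice_spacing=3.0, phase_deg=2.3)
        trainee = perturb(base, 2.0, seed=seed)
        reference = perturb(base, 2.0, seed=seed + 1000)
        prod = compute_lssd_map(trainee, reference, 10.0)
        oracle = lssd_map_bruteforce(trainee, reference, 10.0)
        np.testing.assert_array_equal(prod.valid, oracle.valid)
        assert np.abs(prod.values[prod.valid] - oracle.values[oracle.valid]).max() < 1e-9
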