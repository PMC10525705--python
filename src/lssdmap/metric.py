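"""Localized signed surface distance (LSSD) between a trainee and a reference contour.

For each axial slice the plane is split into ``N = 360 / delta_theta``
angular sectors about the geometric centre of the *reference* contour.  In
each sector the symmetric mean surface distance between the sector's pieces
of the reference boundary (dR) and of the trainee boundary (dT) is

    |dd| = (d_RT + d_TR) / 2,
    d_RT = mean over r in dR of  min over t in dT of ||r - t||,
    d_TR = mean over t in dT of  min over r in dR of ||t - r||.

The enclosed regions clipped to the sector wedge give a per-sector
sensitivity ``P = area(R ∩ T) / area(R)`` and specificity
``Q = area(R ∩ T) / area(T)``; the sector distance is signed positive when
``P >= Q`` (the trainee region extends beyond the reference: over-contoured)
and negative when ``P < Q`` (under-contoured).

All sectors and slices assemble into the LSSD map: rows are CT slices
(ascending z), columns are sectors (ascending start angle).  Map values are
stored unclipped; the +/-3 mm display saturation belongs to rendering only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point

from .geometry import (
    ContourError,
    SectorGrid,
    SliceContour,
    StructureContours,
    boundary_points,
    build_sector_grid,
    sector_indices,
    slice_centroid,
    wedge_polygon,
)

logger = logging.getLogger(__name__)

#: Default boundary resampling step for the distance computation, mm.
DEFAULT_RESAMPLE_MM = 0.25

# cell status codes
STATUS_DEFINED = "defined"
STATUS_EMPTY_TRAINEE = "empty_trainee"
STATUS_EMPTY_REFERENCE = "empty_reference"
STATUS_BOTH_EMPTY = "both_empty"
STATUS_TRAINEE_MISSING_SLICE = "trainee_missing_slice"
STATUS_REFERENCE_MISSING_SLICE = "reference_missing_slice"

_AREA_EPS = 1e-9  # mm^2


@dataclass(frozen=True)
class SectorMeasurement:
    """One sector's distance, overlap ratios and sign."""

    slice_index: int
    sector_index: int
    abs_distance: float
    sensitivity: float | None
    specificity: float | None
    signed_distance: float
    status: str = STATUS_DEFINED


@dataclass
class LSSDMap:
    """Slice-by-sector signed distance map.

    ``values[i, k]`` is the signed distance (mm) on the i-th slice
    (ascending z) in sector k (start angle ``k * delta_theta``); cells with
    ``valid[i, k] == False`` carry no measurement and are excluded from all
    statistics.  ``status`` records why a cell is defined or not.
    """

    values: np.ndarray
    valid: np.ndarray
    z_positions: np.ndarray
    delta_theta: float
    structure_label: str = "structure"
    sequence_index: int = 0
    status: np.ndarray | None = None
    centroid_outside_slices: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid must share one shape")
        if self.status is None:
            self.status = np.where(self.valid, STATUS_DEFINED, STATUS_BOTH_EMPTY).astype(object)

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def n_sectors(self) -> int:
        return self.values.shape[1]

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]

    def sector_start_angles(self) -> np.ndarray:
        return np.arange(self.n_sectors) * self.delta_theta


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def directed_mean_distance(points: np.ndarray, pool: np.ndarray) -> float:
    """Mean over ``points`` of the distance to the nearest member of ``pool``."""
    if len(points) == 0 or len(pool) == 0:
        raise ContourError("directed_mean_distance requires non-empty point sets")
    d, _ = cKDTree(pool).query(points)
    return float(np.mean(d))


def sector_mean_distance(ref_points: np.ndarray, trainee_points: np.ndarray) -> float:
    """Symmetric mean surface distance |dd| between two boundary point sets."""
    d_rt = directed_mean_distance(ref_points, trainee_points)
    d_tr = directed_mean_distance(trainee_points, ref_points)
    return 0.5 * (d_rt + d_tr)


def sector_overlap_ratios(
    ref_region_area: float, trainee_region_area: float, intersection_area: float
) -> tuple[float, float]:
    """Sensitivity P and specificity Q of the trainee region within a sector.

    P = intersection / reference area, Q = intersection / trainee area.
    """
    if ref_region_area < 0 or trainee_region_area < 0 or intersection_area < 0:
        raise ValueError("areas must be non-negative")
    if intersection_area > min(ref_region_area, trainee_region_area) + 1e-6:
        raise ValueError("intersection area exceeds a region area")
    if ref_region_area <= _AREA_EPS or trainee_region_area <= _AREA_EPS:
        raise ContourError("overlap ratios undefined for an empty region")
    return (intersection_area / ref_region_area, intersection_area / trainee_region_area)


def sign_distance(abs_distance: float, sensitivity: float, specificity: float) -> float:
    """Apply the over/under-contouring sign: +|dd| when P >= Q, else -|dd|."""
    if abs_distance < 0:
        raise ValueError("abs_distance must be >= 0")
    return abs_distance if sensitivity >= specificity else -abs_distance


# ---------------------------------------------------------------------------
# per-slice sector sweep
# ---------------------------------------------------------------------------

def _slice_sectors(
    ref_slice: SliceContour,
    trainee_slice: SliceContour,
    delta_theta: float,
    resample_mm: float,
) -> tuple[np.ndarray, np.ndarray, list[str], bool]:
    """Signed distances for every sector of one slice.

    Returns (values, valid, statuses, centroid_inside_reference).
    """
    n = int(round(360.0 / delta_theta))
    origin = slice_centroid(ref_slice)
    ref_poly = ref_slice.polygon
    tr_poly = trainee_slice.polygon
    inter_poly = ref_poly.intersection(tr_poly)

    ref_pts = boundary_points(ref_slice, resample_mm)
    tr_pts = boundary_points(trainee_slice, resample_mm)
    ref_sec = sector_indices(ref_pts, origin, delta_theta)
    tr_sec = sector_indices(tr_pts, origin, delta_theta)

    all_pts = np.vstack([ref_pts, tr_pts])
    max_r = float(np.max(np.hypot(all_pts[:, 0] - origin[0], all_pts[:, 1] - origin[1])))
    wedge_radius = 2.0 * max(max_r, 1.0)

    values = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    statuses = [STATUS_BOTH_EMPTY] * n

    for k in range(n):
        wedge = wedge_polygon(origin, k * delta_theta, (k + 1) * delta_theta, wedge_radius)
        ra = ref_poly.intersection(wedge).area
        ta = tr_poly.intersection(wedge).area
        ia = inter_poly.intersection(wedge).area if not inter_poly.is_empty else 0.0
        rp = ref_pts[ref_sec == k]
        tp = tr_pts[tr_sec == k]

        if ra > _AREA_EPS and ta > _AREA_EPS:
            # both regions reach the wedge: the regular distance + sign cell
            terms = []
            if len(rp):
                pool_t = tp if len(tp) else tr_pts
                terms.append(directed_mean_distance(rp, pool_t))
            if len(tp):
                pool_r = rp if len(rp) else ref_pts
                terms.append(directed_mean_distance(tp, pool_r))
            if not terms:
                continue  # neither boundary crosses the wedge: unmeasurable
            abs_d = float(np.mean(terms)) if len(terms) == 2 else terms[0]
            p, q = sector_overlap_ratios(ra, ta, ia)
            values[k] = sign_distance(abs_d, p, q)
            valid[k] = True
            statuses[k] = STATUS_DEFINED
        elif ta <= _AREA_EPS < ra and len(rp):
            # trainee region absent from the wedge: forced under-contour sign
            values[k] = -directed_mean_distance(rp, tr_pts)
            valid[k] = True
            statuses[k] = STATUS_EMPTY_TRAINEE
        elif ra <= _AREA_EPS < ta and len(tp):
            values[k] = +directed_mean_distance(tp, ref_pts)
            valid[k] = True
            statuses[k] = STATUS_EMPTY_REFERENCE
        # else: both regions miss the wedge -> cell stays masked

    centroid_inside = ref_poly.covers(Point(origin))
    return values, valid, statuses, bool(centroid_inside)


# ---------------------------------------------------------------------------
# map assembly
# ---------------------------------------------------------------------------

def compute_lssd_map(
    trainee: StructureContours,
    reference: StructureContours,
    delta_theta: float = 10.0,
    resample_mm: float = DEFAULT_RESAMPLE_MM,
    sequence_index: int = 0,
) -> LSSDMap:
    """Assemble the slice-by-sector LSSD map of trainee vs reference.

    Slices are matched in z within half a slice spacing.  A slice present in
    only one structure beyond the other's superior/inferior extent produces a
    whole row with the corresponding forced sign and magnitude equal to the
    z overshoot (slice spacing times the number of slices beyond the other
    structure's extent), flagged by a dedicated row status.
    """
    if trainee.is_empty or reference.is_empty:
        raise ContourError("compute_lssd_map requires non-empty trainee and reference")
    # sector grid validation (delta_theta divides 360)
    build_sector_grid(reference, delta_theta)
    n = int(round(360.0 / delta_theta))
    spacing = reference.slice_spacing
    tol = 0.5 * spacing

    ref_z = reference.z_positions
    tr_z = trainee.z_positions
    # pair slices on a common z ladder; flag interior mismatches
    rows: list[tuple[float, SliceContour | None, SliceContour | None]] = []
    mismatched: list[float] = []
    used_tr = np.zeros(len(tr_z), dtype=bool)
    for rs in reference.slices:
        j = np.argmin(np.abs(tr_z - rs.z)) if len(tr_z) else None
        if j is not None and abs(tr_z[j] - rs.z) <= tol:
            rows.append((rs.z, rs, trainee.slices[int(j)]))
            used_tr[int(j)] = True
        else:
            rows.append((rs.z, rs, None))
            if tr_z.min() - tol <= rs.z <= tr_z.max() + tol:
                mismatched.append(rs.z)
    for j, ts in enumerate(trainee.slices):
        if not used_tr[j]:
            rows.append((ts.z, None, ts))
            if ref_z.min() - tol <= ts.z <= ref_z.max() + tol:
                mismatched.append(ts.z)
    if mismatched:
        raise ContourError(
            "trainee/reference z grids do not align at slices "
            f"z={sorted(set(mismatched))} (tolerance {tol:.3g} mm)"
        )
    rows.sort(key=lambda r: r[0])

    values = np.full((len(rows), n), np.nan)
    valid = np.zeros((len(rows), n), dtype=bool)
    status = np.full((len(rows), n), STATUS_BOTH_EMPTY, dtype=object)
    centroid_out: list[float] = []

    for i, (z, rs, ts) in enumerate(rows):
        if rs is not None and ts is not None:
            v, m, st, inside = _slice_sectors(rs, ts, delta_theta, resample_mm)
            values[i], valid[i] = v, m
            status[i] = np.asarray(st, dtype=object)
            if not inside:
                centroid_out.append(z)
                logger.warning(
                    "reference centroid lies outside the reference region on slice z=%.2f", z
                )
        elif rs is not None:
            # reference extends beyond the trainee in z: under-contoured row
            overshoot = max(tr_z.min() - z, z - tr_z.max())
            k_slices = max(1, int(round(overshoot / spacing)))
            values[i] = -k_slices * spacing
            valid[i] = True
            status[i] = STATUS_TRAINEE_MISSING_SLICE
        else:
            overshoot = max(ref_z.min() - z, z - ref_z.max())
            k_slices = max(1, int(round(overshoot / spacing)))
            values[i] = +k_slices * spacing
            valid[i] = True
            status[i] = STATUS_REFERENCE_MISSING_SLICE

    return LSSDMap(
        values=values,
        valid=valid,
        z_positions=np.array([r[0] for r in rows]),
        delta_theta=float(delta_theta),
        structure_label=reference.label or trainee.label,
        sequence_index=sequence_index,
        status=status,
        centroid_outside_slices=tuple(centroid_out),
    )
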