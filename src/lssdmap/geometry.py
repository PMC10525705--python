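"""Planar contour geometry in the patient frame.

Contours of one anatomical structure are stored slice by slice as ordered
vertex rings in patient millimetres (DICOM head-first-supine axes: +x is
patient left, +y is patient posterior, +z superior).  This module provides
the geometric substrate for the sector-based signed-distance metric:
centroids, angular sector grids, boundary resampling and polygon/mask
conversion.

Angle convention
----------------
Sector angles follow the clinical reading of an axial slice in a head-first
supine setup: ``theta = atan2(-(y - y0), x - x0)`` mapped to [0, 360) degrees,
so 0 deg points patient-left, 90 deg anterior, 180 deg right and 270 deg
posterior.  This function is the single place where the patient frame is
interpreted.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union
from skimage import measure

logger = logging.getLogger(__name__)

#: Sector widths (degrees) accepted by :func:`build_sector_grid`.
VALID_SECTOR_WIDTHS = tuple(d for d in range(1, 361) if 360 % d == 0)

_MIN_RING_AREA = 1e-9  # mm^2; rings below this are considered degenerate


class ContourError(ValueError):
    """Invalid contour geometry (degenerate ring, inconsistent slice grid...)."""


def _clean_ring(ring: np.ndarray) -> Polygon:
    """Build a valid shapely polygon from an ordered vertex ring."""
    poly = Polygon(ring)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


@dataclass(frozen=True)
class SliceContour:
    """Ordered polygon ring(s) of one structure on one axial slice.

    Parameters
    ----------
    z:
        Slice position in patient mm.
    rings:
        Tuple of ``(n, 2)`` float arrays of (x, y) vertices in patient mm.
        Rings are open (the closing edge back to the first vertex is
        implicit).  Each ring must have at least 3 vertices and enclose a
        nonzero area.
    """

    z: float
    rings: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if not self.rings:
            raise ContourError(f"slice z={self.z}: no rings")
        cleaned = []
        for ring in self.rings:
            arr = np.asarray(ring, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise ContourError(
                    f"slice z={self.z}: ring needs >= 3 (x, y) vertices, got shape {arr.shape}"
                )
            # drop an explicit closing vertex
            if np.allclose(arr[0], arr[-1]):
                arr = arr[:-1]
            if arr.shape[0] < 3:
                raise ContourError(f"slice z={self.z}: degenerate ring after closure removal")
            poly = _clean_ring(arr)
            if poly.area <= _MIN_RING_AREA:
                raise ContourError(f"slice z={self.z}: ring encloses (near-)zero area")
            cleaned.append(np.ascontiguousarray(arr))
        object.__setattr__(self, "rings", tuple(cleaned))

    @property
    def polygon(self):
        """Union of all rings as a shapely (Multi)Polygon."""
        return unary_union([_clean_ring(r) for r in self.rings])

    @property
    def area(self) -> float:
        return float(self.polygon.area)

    def translated(self, dx: float, dy: float) -> "SliceContour":
        return SliceContour(self.z, tuple(r + np.array([dx, dy]) for r in self.rings))


@dataclass(frozen=True)
class StructureContours:
    """Stack of :class:`SliceContour` for one structure on one image series."""

    label: str
    slices: tuple[SliceContour, ...]
    slice_spacing: float

    def __post_init__(self) -> None:
        if self.slice_spacing <= 0:
            raise ContourError(f"{self.label}: slice_spacing must be > 0")
        object.__setattr__(self, "slices", tuple(sorted(self.slices, key=lambda s: s.z)))
        zs = self.z_positions
        if len(zs) > 1:
            gaps = np.diff(zs)
            if np.any(gaps <= 0):
                raise ContourError(f"{self.label}: z positions must be strictly increasing")
            # gaps must be (integer multiples of) the slice spacing; missing
            # slices are allowed, irregular grids are not
            mult = gaps / self.slice_spacing
            if np.any(np.abs(mult - np.round(mult)) > 1e-3) or np.any(np.round(mult) < 1):
                raise ContourError(
                    f"{self.label}: slice gaps {gaps} inconsistent with spacing {self.slice_spacing}"
                )

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([s.z for s in self.slices], dtype=float)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def is_empty(self) -> bool:
        return not self.slices

    def slice_at(self, z: float, tol: float | None = None) -> SliceContour | None:
        """Return the slice within ``tol`` of z (default: half the slice spacing)."""
        tol = 0.5 * self.slice_spacing if tol is None else tol
        for s in self.slices:
            if abs(s.z - z) <= tol:
                return s
        return None

    def translated(self, dx: float, dy: float) -> "StructureContours":
        return StructureContours(
            self.label, tuple(s.translated(dx, dy) for s in self.slices), self.slice_spacing
        )


@dataclass(frozen=True)
class SectorGrid:
    """Angular partition of each slice, anchored at the reference centroid.

    Sector ``k`` covers the half-open angular interval
    ``[k * delta_theta, (k + 1) * delta_theta)`` degrees under the patient
    frame convention (0 deg = patient left, 90 deg = anterior).
    """

    delta_theta: float
    n_sectors: int
    origin_per_slice: dict[float, tuple[float, float]] = field(default_factory=dict)

    def sector_start_angles(self) -> np.ndarray:
        return np.arange(self.n_sectors) * self.delta_theta


@dataclass(frozen=True)
class MaskVolume:
    """Binary voxel volume with axis order (z, y, x) in the patient frame.

    Voxel ``(k, j, i)`` has its centre at
    ``origin + (i * dx, j * dy, k * dz)``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels).astype(bool)
        object.__setattr__(self, "voxels", vox)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing components must be > 0, got {self.spacing}")
        if vox.ndim != 3:
            raise ValueError(f"voxels must be 3D (z, y, x), got ndim={vox.ndim}")

    @property
    def foreground_count(self) -> int:
        return int(self.voxels.sum())

    def same_grid(self, other: "MaskVolume", tol: float = 1e-6) -> bool:
        return (
            self.voxels.shape == other.voxels.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def dice(self, other: "MaskVolume") -> float:
        if not self.same_grid(other):
            raise ValueError("Dice requires masks on the same grid")
        a, b = self.voxels, other.voxels
        denom = a.sum() + b.sum()
        if denom == 0:
            return 1.0
        return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


# ---------------------------------------------------------------------------
# centroids and sector grids
# ---------------------------------------------------------------------------

def slice_centroid(contour: SliceContour) -> tuple[float, float]:
    """Area-weighted geometric centre of the union of a slice's rings."""
    poly = contour.polygon
    if poly.area <= _MIN_RING_AREA:
        raise ContourError(f"slice z={contour.z}: zero-area contour has no centroid")
    c = poly.centroid
    return (float(c.x), float(c.y))


def point_angles(points: np.ndarray, origin: tuple[float, float]) -> np.ndarray:
    """Sector angles in degrees, [0, 360), of (n, 2) points about origin.

    0 deg is patient-left (+x), 90 deg anterior (-y) for HFS DICOM axes.
    """
    pts = np.asarray(points, dtype=float)
    dx = pts[:, 0] - origin[0]
    dy = pts[:, 1] - origin[1]
    return np.degrees(np.arctan2(-dy, dx)) % 360.0


def build_sector_grid(reference: StructureContours, delta_theta: float) -> SectorGrid:
    """Angular sector grid anchored at the reference contour's per-slice centroid.

    ``delta_theta`` must divide 360 exactly so the N = 360 / delta_theta
    sectors tile the circle without a partial wrap-around sector.
    """
    if delta_theta not in VALID_SECTOR_WIDTHS:
        raise ValueError(
            f"delta_theta={delta_theta} does not divide 360; "
            f"valid widths are {VALID_SECTOR_WIDTHS}"
        )
    if reference.is_empty:
        raise ContourError("cannot build a sector grid from an empty reference")
    n = int(round(360.0 / delta_theta))
    origins = {s.z: slice_centroid(s) for s in reference.slices}
    return SectorGrid(delta_theta=float(delta_theta), n_sectors=n, origin_per_slice=origins)


def sector_membership(
    point: tuple[float, float], origin: tuple[float, float], grid: SectorGrid
) -> int:
    """Index of the sector containing ``point`` about ``origin``."""
    dx = point[0] - origin[0]
    dy = point[1] - origin[1]
    if dx == 0.0 and dy == 0.0:
        logger.warning("point coincides with sector origin; assigning sector 0")
        return 0
    theta = math.degrees(math.atan2(-dy, dx)) % 360.0
    return int(theta // grid.delta_theta) % grid.n_sectors


def sector_indices(points: np.ndarray, origin: tuple[float, float], delta_theta: float) -> np.ndarray:
    """Vectorized sector index for every point (see :func:`sector_membership`)."""
    theta = point_angles(points, origin)
    n = int(round(360.0 / delta_theta))
    return np.minimum((theta // delta_theta).astype(int), n - 1)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_ring(ring: np.ndarray, max_spacing: float) -> np.ndarray:
    """Densify a ring so consecutive points are at most ``max_spacing`` apart.

    Input vertices are preserved; extra points are linearly interpolated
    along each edge.  The output is closed (last point equals the first).
    """
    if max_spacing <= 0:
        raise ValueError("max_spacing must be > 0")
    arr = np.asarray(ring, dtype=float)
    if np.allclose(arr[0], arr[-1]):
        arr = arr[:-1]
    if arr.shape[0] < 3:
        raise ContourError("ring needs >= 3 distinct vertices")
    out = []
    n = arr.shape[0]
    for i in range(n):
        a = arr[i]
        b = arr[(i + 1) % n]
        out.append(a)
        edge = np.linalg.norm(b - a)
        if edge > max_spacing:
            k = int(math.ceil(edge / max_spacing))
            for j in range(1, k):
                out.append(a + (b - a) * (j / k))
    out.append(arr[0])
    return np.asarray(out)


def boundary_points(contour: SliceContour, max_spacing: float) -> np.ndarray:
    """Pooled resampled boundary points of all rings (open: no duplicated closure)."""
    parts = [resample_ring(r, max_spacing)[:-1] for r in contour.rings]
    return np.vstack(parts)


# ---------------------------------------------------------------------------
# sector wedges
# ---------------------------------------------------------------------------

def wedge_polygon(
    origin: tuple[float, float], a_start: float, a_end: float, radius: float
) -> Polygon:
    """Convex polygon covering the angular wedge [a_start, a_end] out to ``radius``.

    The arc is approximated by chords placed slightly beyond ``radius`` so
    that the polygon strictly contains the true circular wedge; geometry
    clipped with it must lie within ``radius`` of the origin.
    """
    span = a_end - a_start
    if span <= 0:
        raise ValueError("a_end must exceed a_start")
    if span >= 360.0:
        return shapely.geometry.Point(origin).buffer(radius * 1.05, quad_segs=64)
    n_arc = max(2, int(math.ceil(span / 5.0)) + 1)
    angles = np.linspace(a_start, a_end, n_arc)
    r_out = radius / math.cos(math.radians(span / (n_arc - 1)) / 2.0)
    rad = np.radians(angles)
    xs = origin[0] + r_out * np.cos(rad)
    ys = origin[1] - r_out * np.sin(rad)
    pts = [(origin[0], origin[1])] + list(zip(xs, ys))
    return Polygon(pts)


# ---------------------------------------------------------------------------
# polygon <-> mask conversion
# ---------------------------------------------------------------------------

def polygons_to_mask(
    structure: StructureContours,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] | None = None,
    shape: tuple[int, int, int] | None = None,
) -> MaskVolume:
    """Rasterize a contour stack onto a voxel grid by voxel-centre sampling.

    If ``origin``/``shape`` are omitted, a grid is fitted to the structure's
    bounding box with a 2-voxel margin in-plane.  Voxel centres covered by
    (or on the boundary of) the union of a slice's rings become foreground.
    """
    dx, dy, dz = spacing
    if dx <= 0 or dy <= 0 or dz <= 0:
        raise ValueError("spacing components must be > 0")
    if structure.is_empty:
        if origin is None or shape is None:
            raise ContourError("empty structure: cannot infer a raster grid")
        warnings.warn("rasterizing an empty structure -> all-zero mask", stacklevel=2)
        return MaskVolume(np.zeros(shape, dtype=bool),
                          (float(dx), float(dy), float(dz)), tuple(map(float, origin)))
    zs = structure.z_positions
    if origin is None or shape is None:
        bounds = np.array([_clean_ring(r).bounds for s in structure.slices for r in s.rings])
        xmin, ymin = bounds[:, 0].min(), bounds[:, 1].min()
        xmax, ymax = bounds[:, 2].max(), bounds[:, 3].max()
        x0 = xmin - 2 * dx
        y0 = ymin - 2 * dy
        z0 = float(zs.min())
        nx = int(math.ceil((xmax + 2 * dx - x0) / dx)) + 1
        ny = int(math.ceil((ymax + 2 * dy - y0) / dy)) + 1
        nz = int(round((zs.max() - zs.min()) / dz)) + 1
        origin = (float(x0), float(y0), z0)
        shape = (nz, ny, nx)
    nz, ny, nx = shape
    vox = np.zeros(shape, dtype=bool)
    xc = origin[0] + np.arange(nx) * dx
    yc = origin[1] + np.arange(ny) * dy
    X, Y = np.meshgrid(xc, yc)  # (ny, nx)
    for s in structure.slices:
        k = int(round((s.z - origin[2]) / dz))
        if k < 0 or k >= nz:
            continue
        poly = s.polygon
        shapely.prepare(poly)
        vox[k] = shapely.intersects_xy(poly, X, Y)
    return MaskVolume(vox, (float(dx), float(dy), float(dz)), tuple(map(float, origin)))


def mask_to_polygons(mask: MaskVolume, label: str = "structure") -> StructureContours:
    """Extract per-slice iso-0.5 boundary polygons from a binary volume.

    Contours are placed at voxel-centre coordinates (marching squares at
    level 0.5); slices with no foreground are omitted.
    """
    dx, dy, dz = mask.spacing
    x0, y0, z0 = mask.origin
    slices = []
    for k in range(mask.voxels.shape[0]):
        plane = mask.voxels[k]
        if not plane.any():
            continue
        padded = np.pad(plane.astype(float), 1)
        rings = []
        for coords in measure.find_contours(padded, 0.5):
            rows = coords[:, 0] - 1.0
            cols = coords[:, 1] - 1.0
            ring = np.column_stack([x0 + cols * dx, y0 + rows * dy])
            if ring.shape[0] < 4:
                continue
            poly = Polygon(ring)
            if not poly.is_valid:
                poly = poly.buffer(0)
            if poly.area <= max(_MIN_RING_AREA, 0.25 * dx * dy):
                continue
            rings.append(ring)
        if rings:
            slices.append(SliceContour(z=z0 + k * dz, rings=tuple(rings)))
    if not slices:
        warnings.warn("mask has no extractable contours; returning empty is not allowed",
                      stacklevel=2)
        raise ContourError("empty mask: no contours to extract")
    return StructureContours(label=label, slices=tuple(slices), slice_spacing=dz)
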