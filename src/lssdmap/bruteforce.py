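"""Slow, literal reference implementation of the sector signed-distance sweep.

This module recomputes the LSSD map with deliberately naive machinery so the
production path (:func:`lssdmap.metric.compute_lssd_map`) can be validated
against it:

* per-point angular binning with scalar ``math.atan2`` loops;
* exhaustive nearest-neighbour search via full pairwise distance matrices
  (no spatial index);
* sector wedge areas by Sutherland–Hodgman half-plane clipping of the
  region rings followed by the shoelace formula (no shapely wedge
  intersection).

Shapely is used only to canonicalize the input regions (union of a slice's
rings and the reference∩trainee intersection region); everything per sector
is computed here from first principles.  Rings of one slice are assumed
disjoint.  Both structures must share the same z ladder.

This implementation is O(n·m) per sector and intended for validation on
small fixtures only.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import MultiPolygon, Polygon

from .geometry import StructureContours, boundary_points, slice_centroid
from .metric import (
    STATUS_BOTH_EMPTY,
    STATUS_DEFINED,
    STATUS_EMPTY_REFERENCE,
    STATUS_EMPTY_TRAINEE,
    LSSDMap,
)

_AREA_EPS = 1e-9


# ---------------------------------------------------------------------------
# naive primitives
# ---------------------------------------------------------------------------

def _angles_deg(points: np.ndarray, origin: tuple[float, float]) -> list[float]:
    out = []
    for x, y in points:
        out.append(math.degrees(math.atan2(-(y - origin[1]), x - origin[0])) % 360.0)
    return out


def _mean_min_distance(points: np.ndarray, pool: np.ndarray) -> float:
    """Mean nearest-neighbour distance by explicit distance matrix."""
    diff = points[:, None, :] - pool[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return float(d.min(axis=1).sum() / len(points))


def _clip_halfplane(vertices: list[tuple[float, float]], normal: tuple[float, float]):
    """Sutherland–Hodgman clip of a polygon against ``normal . u >= 0``."""
    if not vertices:
        return []
    out: list[tuple[float, float]] = []
    nx, ny = normal
    m = len(vertices)
    for i in range(m):
        px, py = vertices[i]
        qx, qy = vertices[(i + 1) % m]
        dp = nx * px + ny * py
        dq = nx * qx + ny * qy
        if dp >= 0.0:
            out.append((px, py))
        if (dp >= 0.0) != (dq >= 0.0):
            t = dp / (dp - dq)
            out.append((px + t * (qx - px), py + t * (qy - py)))
    return out


def _shoelace(vertices) -> float:
    if len(vertices) < 3:
        return 0.0
    a = 0.0
    m = len(vertices)
    for i in range(m):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % m]
        a += x1 * y2 - x2 * y1
    return abs(a) / 2.0


def _wedge_clipped_area(
    region, origin: tuple[float, float], a_start: float, a_end: float
) -> float:
    """Area of ``region`` inside the angular wedge [a_start, a_end] about origin.

    The wedge spans < 180 degrees and is the intersection of two half-planes
    through the origin; clipping happens in a local frame ``u = (x - x0,
    -(y - y0))`` where the sector angle is the ordinary CCW polar angle.
    """
    span = a_end - a_start
    if not (0.0 < span < 180.0):
        raise ValueError("wedge span must be in (0, 180) degrees")
    r1, r2 = math.radians(a_start), math.radians(a_end)
    n1 = (-math.sin(r1), math.cos(r1))   # keeps angles >= a_start
    n2 = (math.sin(r2), -math.cos(r2))   # keeps angles <= a_end

    if region.is_empty:
        return 0.0
    if isinstance(region, Polygon):
        polys = [region]
    elif isinstance(region, MultiPolygon):
        polys = list(region.geoms)
    else:  # GeometryCollection from degenerate intersections
        polys = [g for g in region.geoms if isinstance(g, Polygon)]

    total = 0.0
    for poly in polys:
        def ring_area(coords) -> float:
            local = [(x - origin[0], -(y - origin[1])) for x, y in coords]
            clipped = _clip_halfplane(local, n1)
            clipped = _clip_halfplane(clipped, n2)
            return _shoelace(clipped)

        total += ring_area(list(poly.exterior.coords)[:-1])
        for hole in poly.interiors:
            total -= ring_area(list(hole.coords)[:-1])
    return total


# ---------------------------------------------------------------------------
# map computation
# ---------------------------------------------------------------------------

def lssd_map_bruteforce(
    trainee: StructureContours,
    reference: StructureContours,
    delta_theta: float = 10.0,
    resample_mm: float = 0.25,
) -> LSSDMap:
    """Brute-force LSSD map for structures sharing an identical z ladder."""
    ref_z = reference.z_positions
    tr_z = trainee.z_positions
    if len(ref_z) != len(tr_z) or np.max(np.abs(ref_z - tr_z)) > 0.5 * reference.slice_spacing:
        raise ValueError("brute-force path requires matching z grids")
    if 360.0 % delta_theta != 0:
        raise ValueError("delta_theta must divide 360")
    n = int(round(360.0 / delta_theta))

    values = np.full((len(ref_z), n), np.nan)
    valid = np.zeros((len(ref_z), n), dtype=bool)
    status = np.full((len(ref_z), n), STATUS_BOTH_EMPTY, dtype=object)

    for i, (rs, ts) in enumerate(zip(reference.slices, trainee.slices)):
        origin = slice_centroid(rs)
        ref_poly = rs.polygon
        tr_poly = ts.polygon
        inter_poly = ref_poly.intersection(tr_poly)

        ref_pts = boundary_points(rs, resample_mm)
        tr_pts = boundary_points(ts, resample_mm)
        ref_ang = _angles_deg(ref_pts, origin)
        tr_ang = _angles_deg(tr_pts, origin)

        for k in range(n):
            a0, a1 = k * delta_theta, (k + 1) * delta_theta
            rp = np.array([p for p, a in zip(ref_pts, ref_ang) if a0 <= a < a1])
            tp = np.array([p for p, a in zip(tr_pts, tr_ang) if a0 <= a < a1])
            ra = _wedge_clipped_area(ref_poly, origin, a0, a1)
            ta = _wedge_clipped_area(tr_poly, origin, a0, a1)
            ia = _wedge_clipped_area(inter_poly, origin, a0, a1)

            if ra > _AREA_EPS and ta > _AREA_EPS:
                terms = []
                if len(rp):
                    terms.append(_mean_min_distance(rp, tp if len(tp) else tr_pts))
                if len(tp):
                    terms.append(_mean_min_distance(tp, rp if len(rp) else ref_pts))
                if not terms:
                    continue
                abs_d = sum(terms) / len(terms)
                p = ia / ra
                q = ia / ta
                values[i, k] = abs_d if p >= q else -abs_d
                valid[i, k] = True
                status[i, k] = STATUS_DEFINED
            elif ta <= _AREA_EPS < ra and len(rp):
                values[i, k] = -_mean_min_distance(rp, tr_pts)
                valid[i, k] = True
                status[i, k] = STATUS_EMPTY_TRAINEE
            elif ra <= _AREA_EPS < ta and len(tp):
                values[i, k] = +_mean_min_distance(tp, ref_pts)
                valid[i, k] = True
                status[i, k] = STATUS_EMPTY_REFERENCE

    return LSSDMap(
        values=values,
        valid=valid,
        z_positions=ref_z.copy(),
        delta_theta=float(delta_theta),
        structure_label=reference.label,
        status=status,
    )
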