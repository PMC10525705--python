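"""Readers and writers for contours, masks, LSSD maps and stats tables.

The canonical contour interchange format is a small JSON document::

    {
      "schema_version": 1,
      "case_id": "case01",
      "structure_label": "Heart",
      "frame": "patient-mm-HFS",
      "slice_spacing": 3.0,
      "slices": [{"z": 0.0, "rings": [[[x, y], ...], ...]}, ...]
    }

DICOM RT-STRUCT files can be read (ContourSequence of a named ROI, closed
planar contours, patient mm); writing RT-STRUCT is out of scope.  Mask
volumes round-trip through NIfTI.  LSSD maps round-trip through CSV (rows
labelled by slice z, columns by sector start angle, blank cells invalid)
with a JSON sidecar for the metadata.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .geometry import ContourError, MaskVolume, SliceContour, StructureContours
from .metric import STATUS_BOTH_EMPTY, LSSDMap

SCHEMA_VERSION = 1
FRAME = "patient-mm-HFS"


# ---------------------------------------------------------------------------
# contour JSON
# ---------------------------------------------------------------------------

def write_contours(structure: StructureContours, path: str | Path, case_id: str = "") -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "case_id": case_id,
        "structure_label": structure.label,
        "frame": FRAME,
        "slice_spacing": structure.slice_spacing,
        "slices": [
            {"z": s.z, "rings": [r.tolist() for r in s.rings]} for s in structure.slices
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def _contours_from_doc(doc: dict) -> StructureContours:
    slices = []
    for rec in doc["slices"]:
        rings = tuple(np.asarray(r, dtype=float) for r in rec["rings"])
        for ring in rings:
            if ring.shape[0] < 3:
                raise ContourError(f"slice z={rec['z']}: ring with < 3 vertices")
        slices.append(SliceContour(z=float(rec["z"]), rings=rings))
    zs = [s.z for s in slices]
    if any(b <= a for a, b in zip(zs, zs[1:])):
        raise ContourError("contour document slices are not strictly z-ordered")
    return StructureContours(
        label=doc["structure_label"],
        slices=tuple(slices),
        slice_spacing=float(doc["slice_spacing"]),
    )


def _read_rtstruct(path: Path, roi_name: str) -> StructureContours:
    ds = pydicom.dcmread(str(path), force=True)
    rois = {r.ROIName: int(r.ROINumber) for r in ds.StructureSetROISequence}
    if roi_name not in rois:
        raise KeyError(
            f"ROI {roi_name!r} not found in {path.name}; available ROIs: {sorted(rois)}"
        )
    number = rois[roi_name]
    contour_seq = None
    for rc in ds.ROIContourSequence:
        if int(rc.ReferencedROINumber) == number:
            contour_seq = getattr(rc, "ContourSequence", [])
            break
    if contour_seq is None:
        raise KeyError(f"ROI {roi_name!r} has no contour data in {path.name}")
    by_z: dict[float, list[np.ndarray]] = {}
    for item in contour_seq:
        pts = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
        if pts.shape[0] < 3:
            raise ContourError(f"RT-STRUCT contour at z={pts[0, 2] if len(pts) else '?'}: "
                               "< 3 points")
        z = round(float(np.mean(pts[:, 2])), 3)
        by_z.setdefault(z, []).append(pts[:, :2])
    slices = tuple(
        SliceContour(z=z, rings=tuple(by_z[z])) for z in sorted(by_z)
    )
    zs = sorted(by_z)
    spacing = float(np.min(np.diff(zs))) if len(zs) > 1 else 1.0
    return StructureContours(label=roi_name, slices=slices, slice_spacing=spacing)


def read_contours(
    path: str | Path, format: str | None = None, roi_name: str | None = None
) -> StructureContours:
    """Read a contour stack from canonical JSON or from DICOM RT-STRUCT.

    ``format`` is inferred from the extension when omitted (.json vs .dcm).
    RT-STRUCT reading requires ``roi_name``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"contour file not found: {path}")
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "rtstruct"
    if format == "json":
        return _contours_from_doc(json.loads(path.read_text()))
    if format == "rtstruct":
        if roi_name is None:
            raise ValueError("RT-STRUCT reading requires roi_name")
        return _read_rtstruct(path, roi_name)
    raise ValueError(f"unknown contour format {format!r}")


# ---------------------------------------------------------------------------
# NIfTI masks
# ---------------------------------------------------------------------------

def write_mask(mask: MaskVolume, path: str | Path) -> None:
    # MaskVolume stores (z, y, x); NIfTI canonical order is (x, y, z)
    data = np.transpose(mask.voxels.astype(np.uint8), (2, 1, 0))
    affine = np.diag([*mask.spacing, 1.0])
    affine[:3, 3] = mask.origin
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_mask(path: str | Path) -> MaskVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    affine = img.affine
    spacing = tuple(float(abs(affine[i, i])) for i in range(3))
    origin = tuple(float(affine[i, 3]) for i in range(3))
    if np.any((data != 0) & (data != 1)):
        warnings.warn("non-binary volume; binarizing at 0.5", stacklevel=2)
    vox = np.transpose(data >= 0.5, (2, 1, 0))
    return MaskVolume(vox, spacing, origin)


# ---------------------------------------------------------------------------
# LSSD map CSV (+ JSON sidecar)
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_map_csv(lssd_map: LSSDMap, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        np.where(lssd_map.valid, lssd_map.values, np.nan),
        index=pd.Index(lssd_map.z_positions, name="z_mm"),
        columns=[f"{a:g}" for a in lssd_map.sector_start_angles()],
    )
    df.to_csv(path, float_format="%.9g")
    meta = {
        "delta_theta": lssd_map.delta_theta,
        "structure_label": lssd_map.structure_label,
        "sequence_index": lssd_map.sequence_index,
        "status": lssd_map.status.tolist(),
        "centroid_outside_slices": list(lssd_map.centroid_outside_slices),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_map_csv(path: str | Path) -> LSSDMap:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy(dtype=float)
    valid = ~np.isnan(values)
    delta_theta = 360.0 / values.shape[1]
    kwargs = {}
    side = _sidecar_path(path)
    if side.exists():
        meta = json.loads(side.read_text())
        delta_theta = meta["delta_theta"]
        kwargs = {
            "structure_label": meta["structure_label"],
            "sequence_index": meta["sequence_index"],
            "status": np.asarray(meta["status"], dtype=object),
            "centroid_outside_slices": tuple(meta["centroid_outside_slices"]),
        }
    return LSSDMap(
        values=values,
        valid=valid,
        z_positions=df.index.to_numpy(dtype=float),
        delta_theta=delta_theta,
        **kwargs,
    )


def export_map(
    lssd_map: LSSDMap, path: str | Path, format: str = "csv", saturation: float = 3.0,
    cell_px: int = 8,
) -> None:
    """Write a map as CSV (lossless) or PNG (rendered with the clamped colormap)."""
    if format == "csv":
        write_map_csv(lssd_map, path)
    elif format == "png":
        from PIL import Image

        from .viz import render_map

        rgba = render_map(lssd_map, saturation=saturation, cell_px=cell_px)
        Image.fromarray(rgba).save(str(path))
    else:
        raise ValueError(f"unknown map export format {format!r}")


# ---------------------------------------------------------------------------
# stats tables
# ---------------------------------------------------------------------------

def export_stats(rows: list[dict], path: str | Path) -> pd.DataFrame:
    """Write per-case summary rows (LSSD_AVG/SD initial and final, delta) to CSV.

    Each row mirrors the per-trainee, per-case session summary layout:
    identifiers plus ``lssd_avg_i``, ``lssd_sd_i``, ``lssd_avg_f``,
    ``lssd_sd_f``, ``delta_sd``, ``p_value``.
    """
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
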