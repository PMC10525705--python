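"""Synthetic contour phantoms: tubes, rater panels and training sessions.

No clinical contour data ships with this package.  Everything downstream —
the sector metric, STAPLE fusion and the session statistics — is exercised
on analytically known phantoms: circular/elliptical tubes whose per-slice
areas are closed-form, smooth low-frequency radial perturbations emulating
inter-observer variability, voxel-flip raters with prescribed
sensitivity/specificity for fusion parameter-recovery studies, and a
simulated trainee whose contouring noise decays geometrically across map
updates the way a converging training session does.
"""

from __future__ import annotations

import numpy as np

from .geometry import MaskVolume, SliceContour, StructureContours, polygons_to_mask, slice_centroid
from .staple import RaterEnsemble, TrainingSession
from .stats import SessionRecord


def _slice_zs(z_range: tuple[float, float], slice_spacing: float) -> np.ndarray:
    z0, z1 = z_range
    n = int(round((z1 - z0) / slice_spacing)) + 1
    return z0 + np.arange(max(n, 1)) * slice_spacing


def make_tube(
    shape: str = "circle",
    center: tuple[float, float] = (0.0, 0.0),
    radii: float | tuple[float, float] = 50.0,
    z_range: tuple[float, float] = (0.0, 27.0),
    slice_spacing: float = 3.0,
    n_vertices: int = 128,
    label: str = "structure",
    phase_deg: float = 0.0,
) -> StructureContours:
    """Analytic tube phantom with identical circular or elliptical cross-sections.

    A circle of radius r is approximated by a regular ``n_vertices``-gon
    whose area is ``(n/2) r^2 sin(2 pi / n)`` — within 0.2% of ``pi r^2``
    at the default 128 vertices.  ``phase_deg`` rotates the vertex pattern,
    e.g. to keep vertices off exact sector-boundary angles in equivariance
    tests.
    """
    if shape == "circle":
        a = b = float(radii) if np.isscalar(radii) else float(radii[0])
    elif shape == "ellipse":
        a, b = map(float, radii)
    else:
        raise ValueError(f"unknown tube shape {shape!r}")
    if a <= 0 or b <= 0:
        raise ValueError("radii must be > 0")
    theta = 2.0 * np.pi * np.arange(n_vertices) / n_vertices + np.radians(phase_deg)
    ring = np.column_stack([center[0] + a * np.cos(theta), center[1] + b * np.sin(theta)])
    slices = tuple(SliceContour(z=float(z), rings=(ring.copy(),)) for z in
                   _slice_zs(z_range, slice_spacing))
    return StructureContours(label=label, slices=slices, slice_spacing=slice_spacing)


def perturb(
    structure: StructureContours,
    radial_noise_sd: float,
    smoothness: int = 3,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> StructureContours:
    """Add a smooth random radial perturbation about each slice centroid.

    The perturbation is a random low-frequency Fourier series
    ``f(theta) = sum_{k=1..smoothness} a_k cos(k theta) + b_k sin(k theta)``
    with coefficients drawn N(0, sd^2 / smoothness), so the radial deviation
    pooled over angles and slices has standard deviation ``radial_noise_sd``
    in expectation.  ``radial_noise_sd = 0`` returns the input unchanged;
    the same seed reproduces the same output.
    """
    if radial_noise_sd < 0:
        raise ValueError("radial_noise_sd must be >= 0")
    if radial_noise_sd == 0:
        return structure
    if rng is None:
        rng = np.random.default_rng(seed)
    harmonics = np.arange(1, smoothness + 1)
    scale = radial_noise_sd / np.sqrt(smoothness)
    new_slices = []
    for s in structure.slices:
        cx, cy = slice_centroid(s)
        a = rng.normal(0.0, scale, size=smoothness)
        b = rng.normal(0.0, scale, size=smoothness)
        rings = []
        for ring in s.rings:
            dx = ring[:, 0] - cx
            dy = ring[:, 1] - cy
            r = np.hypot(dx, dy)
            theta = np.arctan2(dy, dx)
            f = (a[None, :] * np.cos(np.outer(theta, harmonics))
                 + b[None, :] * np.sin(np.outer(theta, harmonics))).sum(axis=1)
            r_new = np.maximum(r + f, 0.05 * r)  # keep rings simple / star-shaped
            rings.append(np.column_stack([cx + r_new * np.cos(theta),
                                          cy + r_new * np.sin(theta)]))
        new_slices.append(SliceContour(z=s.z, rings=tuple(rings)))
    return StructureContours(label=structure.label, slices=tuple(new_slices),
                             slice_spacing=structure.slice_spacing)


def radial_dilate(structure: StructureContours, delta_mm: float) -> StructureContours:
    """Move every boundary point radially (about its slice centroid) by delta_mm."""
    new_slices = []
    for s in structure.slices:
        cx, cy = slice_centroid(s)
        rings = []
        for ring in s.rings:
            dx = ring[:, 0] - cx
            dy = ring[:, 1] - cy
            r = np.hypot(dx, dy)
            if np.any(r + delta_mm <= 0):
                raise ValueError("radial erosion collapses the ring")
            f = (r + delta_mm) / r
            rings.append(np.column_stack([cx + dx * f, cy + dy * f]))
        new_slices.append(SliceContour(z=s.z, rings=tuple(rings)))
    return StructureContours(label=structure.label, slices=tuple(new_slices),
                             slice_spacing=structure.slice_spacing)


def make_rater_ensemble(
    truth: StructureContours,
    n_raters: int = 8,
    per_rater_noise_sd: float = 1.5,
    flip_rates: tuple[float, float] | None = None,
    spacing: tuple[float, float, float] | None = None,
    seed: int | None = None,
    case_id: str = "synthetic",
) -> RaterEnsemble:
    """Simulated expert panel around a ground-truth structure.

    Without ``flip_rates`` the raters are independent smooth radial
    perturbations of the truth (contour-based panel).  With
    ``flip_rates=(sensitivity, specificity)`` the truth is rasterized and
    each rater flips foreground voxels off with probability
    ``1 - sensitivity`` and background voxels on with probability
    ``1 - specificity`` (mask-based panel for fusion recovery studies).
    """
    if n_raters < 3:
        raise ValueError(
            f"n_raters={n_raters}: at least 3 expert contours are needed for consensus"
        )
    rng = np.random.default_rng(seed)
    if flip_rates is None:
        raters = tuple(
            perturb(truth, per_rater_noise_sd, rng=rng) for _ in range(n_raters)
        )
        return RaterEnsemble(case_id=case_id, structure_label=truth.label, raters=raters)
    sens, spec = flip_rates
    if not (0.0 < sens <= 1.0 and 0.0 < spec <= 1.0):
        raise ValueError("flip rates must lie in (0, 1]")
    if spacing is None:
        spacing = (1.0, 1.0, truth.slice_spacing)
    truth_mask = polygons_to_mask(truth, spacing)
    masks = []
    for _ in range(n_raters):
        vox = truth_mask.voxels.copy()
        u = rng.random(vox.shape)
        vox = np.where(truth_mask.voxels, u < sens, u < (1.0 - spec))
        masks.append(MaskVolume(vox, truth_mask.spacing, truth_mask.origin))
    return RaterEnsemble(case_id=case_id, structure_label=truth.label,
                         rater_masks=tuple(masks))


def flip_raters_from_mask(
    truth_mask: MaskVolume,
    n_raters: int,
    sensitivity: float,
    specificity: float,
    seed: int | None = None,
) -> list[MaskVolume]:
    """Voxel-flip raters on an explicit grid (for fusion recovery studies)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_raters):
        u = rng.random(truth_mask.voxels.shape)
        vox = np.where(truth_mask.voxels, u < sensitivity, u < (1.0 - specificity))
        out.append(MaskVolume(vox, truth_mask.spacing, truth_mask.origin))
    return out


def simulate_session(
    truth: StructureContours,
    initial_noise_sd: float = 3.0,
    n_updates: int = 6,
    decay: float = 0.5,
    seed: int | None = None,
    n_experts: int = 8,
    expert_noise_sd: float = 1.0,
    delta_theta: float = 10.0,
    spacing_xy: tuple[float, float] = (1.0, 1.0),
) -> SessionRecord:
    """Simulate one training session with a geometrically improving trainee.

    At update t the trainee redraws the structure with radial noise
    ``initial_noise_sd * decay**t``; each update re-fuses the reference
    (trainee + expert panel via STAPLE) and recomputes the LSSD map, exactly
    as the interactive feedback loop does.  ``decay = 1`` models a trainee
    who does not improve.
    """
    if n_updates < 1:
        raise ValueError("n_updates must be >= 1")
    rng = np.random.default_rng(seed)
    ensemble = make_rater_ensemble(
        truth, n_raters=n_experts, per_rater_noise_sd=expert_noise_sd,
        seed=int(rng.integers(2**31)),
    )
    session = TrainingSession(ensemble, delta_theta=delta_theta, spacing_xy=spacing_xy)
    record = SessionRecord()
    for t in range(n_updates):
        trainee = perturb(truth, initial_noise_sd * decay**t, rng=rng)
        record.append(session.submit(trainee))
    return record
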