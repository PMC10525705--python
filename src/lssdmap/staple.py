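"""Consensus contour estimation by STAPLE (EM label fusion).

The reference contour used by the LSSD metric is not a gold standard drawn
by any single expert: it is the Simultaneous Truth and Performance Level
Estimation (STAPLE) consensus of the trainee's contour fused with a panel of
expert contours.  STAPLE runs expectation-maximization over the rater
decision matrix D (raters x voxels):

E-step::

    a_i = gamma * prod_j p_j^D_ij (1 - p_j)^(1 - D_ij)
    b_i = (1 - gamma) * prod_j q_j^(1 - D_ij) (1 - q_j)^D_ij
    W_i = a_i / (a_i + b_i)

M-step::

    p_j = sum_i W_i D_ij / sum_i W_i
    q_j = sum_i (1 - W_i)(1 - D_ij) / sum_i (1 - W_i)

where ``p_j``/``q_j`` are rater j's sensitivity/specificity and ``gamma`` is
the prior foreground probability.  A rater who disagrees with the panel is
assigned low performance and contributes little to the consensus, which is
what makes the fused reference robust to a deviant trainee.

Computation is restricted to the union of the rater foregrounds dilated by a
few voxels, so specificities are estimated against relevant background
rather than the whole scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (
    ContourError,
    MaskVolume,
    StructureContours,
    mask_to_polygons,
    polygons_to_mask,
)
from .metric import LSSDMap, compute_lssd_map

logger = logging.getLogger(__name__)

_P_INIT = 0.99999
_PROB_CLIP = 1e-7


@dataclass(frozen=True)
class RaterEnsemble:
    """Expert contour panel for one case and structure.

    At least three expert raters are required for a meaningful consensus;
    raters may be supplied as contour stacks and/or pre-rasterized masks.
    """

    case_id: str
    structure_label: str
    raters: tuple[StructureContours, ...] = ()
    rater_masks: tuple[MaskVolume, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.raters) if self.raters else len(self.rater_masks)
        if n < 3:
            raise ValueError(
                f"ensemble has {n} raters; at least 3 expert contours are needed "
                "for consensus estimation"
            )

    @property
    def n_raters(self) -> int:
        return len(self.raters) if self.raters else len(self.rater_masks)


@dataclass
class StapleResult:
    """Consensus probability volume and per-rater performance estimates."""

    consensus_prob: np.ndarray
    consensus_mask: MaskVolume
    per_rater_sensitivity: np.ndarray
    per_rater_specificity: np.ndarray
    iterations: int
    converged: bool
    log_likelihoods: np.ndarray = field(default_factory=lambda: np.array([]))


def staple(
    masks: list[MaskVolume],
    prior: float | str = "auto",
    tol: float = 1e-6,
    max_iter: int = 100,
    crop_margin: int = 5,
) -> StapleResult:
    """Run binary STAPLE EM over rater masks sharing one voxel grid.

    Parameters
    ----------
    masks:
        Two or more binary volumes on an identical grid.
    prior:
        Foreground prior gamma; ``"auto"`` uses the mean foreground fraction
        of the rater masks over the cropped working region.
    tol:
        Convergence threshold on the relative change of ``sum_i W_i``.
    crop_margin:
        Dilation (voxels) of the union foreground defining the working
        region; background far from every rater is excluded.
    """
    if len(masks) < 2:
        raise ValueError("staple requires at least 2 rater masks")
    base = masks[0]
    for m in masks[1:]:
        if not m.same_grid(base):
            raise ValueError("all rater masks must share one voxel grid")
    stack = np.stack([m.voxels for m in masks])  # (raters, z, y, x)
    union = stack.any(axis=0)
    if not union.any():
        raise ContourError("all rater masks are empty; nothing to fuse")

    region = ndimage.binary_dilation(union, iterations=crop_margin)
    D = stack[:, region].astype(float)  # (raters, voxels)
    n_raters, n_vox = D.shape

    gamma = float(D.mean()) if prior == "auto" else float(prior)
    if not (0.0 < gamma < 1.0):
        raise ValueError(f"prior gamma must lie in (0, 1), got {gamma}")

    p = np.full(n_raters, _P_INIT)
    q = np.full(n_raters, _P_INIT)
    W = np.full(n_vox, gamma)
    logliks = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        pc = np.clip(p, _PROB_CLIP, 1.0 - _PROB_CLIP)
        qc = np.clip(q, _PROB_CLIP, 1.0 - _PROB_CLIP)
        log_a = np.log(gamma) + D.T @ np.log(pc) + (1.0 - D.T) @ np.log(1.0 - pc)
        log_b = np.log1p(-gamma) + (1.0 - D.T) @ np.log(qc) + D.T @ np.log(1.0 - qc)
        logliks.append(float(np.logaddexp(log_a, log_b).sum()))
        W_new = 1.0 / (1.0 + np.exp(log_b - log_a))

        sum_w = W_new.sum()
        sum_not_w = n_vox - sum_w
        p = (D @ W_new) / sum_w if sum_w > 0 else np.ones(n_raters)
        q = ((1.0 - D) @ (1.0 - W_new)) / sum_not_w if sum_not_w > 0 else np.ones(n_raters)

        change = abs(W_new.sum() - W.sum()) / max(W.sum(), 1.0)
        W = W_new
        if change < tol:
            converged = True
            break

    prob = np.zeros(base.voxels.shape, dtype=float)
    prob[region] = W
    consensus = MaskVolume(prob >= 0.5, base.spacing, base.origin)
    return StapleResult(
        consensus_prob=prob,
        consensus_mask=consensus,
        per_rater_sensitivity=np.clip(p, _PROB_CLIP, 1.0),
        per_rater_specificity=np.clip(q, _PROB_CLIP, 1.0),
        iterations=it,
        converged=converged,
        log_likelihoods=np.asarray(logliks),
    )


# ---------------------------------------------------------------------------
# reference contour construction
# ---------------------------------------------------------------------------

def _common_grid(
    structures: list[StructureContours],
    spacing_xy: tuple[float, float],
    margin_mm: float = 5.0,
) -> tuple[tuple[float, float, float], tuple[float, float, float], tuple[int, int, int]]:
    dx, dy = spacing_xy
    dz = structures[0].slice_spacing
    xmin = ymin = np.inf
    xmax = ymax = -np.inf
    zmin = zmax = None
    for s in structures:
        for sc in s.slices:
            b = sc.polygon.bounds
            xmin, ymin = min(xmin, b[0]), min(ymin, b[1])
            xmax, ymax = max(xmax, b[2]), max(ymax, b[3])
        z = s.z_positions
        zmin = float(z.min()) if zmin is None else min(zmin, float(z.min()))
        zmax = float(z.max()) if zmax is None else max(zmax, float(z.max()))
    origin = (xmin - margin_mm, ymin - margin_mm, zmin)
    nx = int(np.ceil((xmax + margin_mm - origin[0]) / dx)) + 1
    ny = int(np.ceil((ymax + margin_mm - origin[1]) / dy)) + 1
    nz = int(round((zmax - zmin) / dz)) + 1
    return (dx, dy, dz), origin, (nz, ny, nx)


def build_reference(
    trainee: StructureContours,
    ensemble: RaterEnsemble,
    spacing_xy: tuple[float, float] = (1.0, 1.0),
    include_trainee: bool = True,
    **staple_kwargs,
) -> StructureContours:
    """Fuse the trainee contour with the expert panel into the reference contour.

    All contours are rasterized onto one grid (default 1 x 1 mm in-plane at
    the native slice spacing), fused with :func:`staple` — the trainee is a
    full member of the fusion unless ``include_trainee=False`` — and the
    consensus probability is thresholded at 0.5 and traced back to per-slice
    polygons.
    """
    if trainee.is_empty:
        raise ContourError("trainee contour is empty; cannot build a reference")
    if not ensemble.raters:
        raise ValueError("build_reference requires contour-based raters in the ensemble")
    structures = ([trainee] if include_trainee else []) + list(ensemble.raters)
    spacing, origin, shape = _common_grid(structures, spacing_xy)
    masks = [polygons_to_mask(s, spacing, origin=origin, shape=shape) for s in structures]
    result = staple(masks, **staple_kwargs)
    if result.consensus_mask.foreground_count == 0:
        raise ContourError(
            "STAPLE consensus is empty; the trainee contour may be degenerate"
        )
    return mask_to_polygons(result.consensus_mask, label=ensemble.structure_label)


# ---------------------------------------------------------------------------
# training session bookkeeping
# ---------------------------------------------------------------------------

class TrainingSession:
    """One trainee x case x structure feedback loop.

    The session owns the expert panel and the current reference contour.
    The reference is deliberately private: the only feedback surfaced to the
    trainee path is the LSSD map itself (``submit`` returns the map, never
    the reference or the expert contours).
    """

    def __init__(
        self,
        ensemble: RaterEnsemble,
        delta_theta: float = 10.0,
        spacing_xy: tuple[float, float] = (1.0, 1.0),
        **staple_kwargs,
    ) -> None:
        self._ensemble = ensemble
        self._delta_theta = delta_theta
        self._spacing_xy = spacing_xy
        self._staple_kwargs = staple_kwargs
        self._reference: StructureContours | None = None
        self._trainee: StructureContours | None = None
        self.sequence_index = -1
        self.maps: list[LSSDMap] = []

    def submit(self, trainee: StructureContours) -> LSSDMap:
        """Update the trainee contour, refresh the reference, return the new map."""
        self._trainee = trainee
        self.sequence_index += 1
        self._reference = build_reference(
            trainee, self._ensemble, spacing_xy=self._spacing_xy, **self._staple_kwargs
        )
        lssd = compute_lssd_map(
            trainee, self._reference, self._delta_theta, sequence_index=self.sequence_index
        )
        self.maps.append(lssd)
        return lssd


def update_reference(session: TrainingSession) -> LSSDMap:
    """Re-fuse the stored expert panel with the current trainee contour."""
    if session._trainee is None:
        raise RuntimeError("no trainee contour submitted yet")
    return session.submit(session._trainee)
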