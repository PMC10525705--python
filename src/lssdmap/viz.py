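"""Rendering of LSSD maps with the clinical feedback colormap.

Signed distances map onto a diverging blue-green-red scale: exactly green
at 0 mm, fully red at or beyond +saturation (trainee beyond the reference,
over-contoured), fully blue at or beyond -saturation (under-contoured).
The default saturation is 3 mm; values outside the band render identically
to the band edge, but the stored map values are never clamped.  Invalid
cells render neutral grey.  Rows are CT slices with z ascending downward,
columns are sectors with start angle ascending to the right.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colors as mcolors

from .metric import LSSDMap

_GREY = (0.5, 0.5, 0.5, 1.0)


def lssd_colormap() -> mcolors.LinearSegmentedColormap:
    """Diverging blue -> green -> red colormap with grey for masked cells."""
    cmap = mcolors.LinearSegmentedColormap.from_list(
        "lssd", [(0.0, 0.0, 1.0), (0.0, 1.0, 0.0), (1.0, 0.0, 0.0)], N=511
    )
    cmap.set_bad(_GREY)
    return cmap


def map_to_rgba(
    values: np.ndarray, valid: np.ndarray, saturation: float = 3.0
) -> np.ndarray:
    """Per-cell RGBA (float, 0..1) of a signed-distance array."""
    if saturation <= 0:
        raise ValueError("saturation must be > 0")
    cmap = lssd_colormap()
    norm = mcolors.Normalize(vmin=-saturation, vmax=saturation, clip=True)
    masked = np.ma.masked_array(values, mask=~np.asarray(valid, dtype=bool))
    return cmap(norm(masked))


def render_map(lssd_map: LSSDMap, saturation: float = 3.0, cell_px: int = 8) -> np.ndarray:
    """Render a map to a uint8 RGBA image, one (cell_px x cell_px) block per cell.

    The image has shape ``(n_slices * cell_px, n_sectors * cell_px, 4)``;
    row 0 is the most inferior slice (lowest z), column 0 the sector starting
    at 0 degrees (patient left).
    """
    if cell_px < 1:
        raise ValueError("cell_px must be >= 1")
    rgba = map_to_rgba(lssd_map.values, lssd_map.valid, saturation)
    img = np.kron(rgba, np.ones((cell_px, cell_px, 1)))
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)
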