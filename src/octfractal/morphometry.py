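"""Layer thickness and RPE-normalized reflectivity.

Thickness is a geometric quantity: the mean over A-scans of the
real-valued (sub-pixel) distance between the two boundaries delimiting a
layer, converted to microns.  Because layers tile the retina with shared
boundaries (half-open intervals), the seven layer thicknesses sum exactly
to the total retinal thickness.

Reflectivity is an optical quantity: the mean layer intensity divided by
the mean RPE intensity over the same A-scans, which cancels global gain.
Vessel-shadow columns are excluded from reflectivity (they attenuate the
signal) but not from thickness (boundaries remain valid under shadows).
"""

from __future__ import annotations

import numpy as np

from .layers import check_layer, layer_bounds
from .oct_io import BScan, LayerSegmentation
from .preprocess import ShadowMask


def layer_thickness(
    seg: LayerSegmentation, layer: str, axial_pitch: float
) -> float:
    """Mean thickness of ``layer`` in microns over all A-scans."""
    ui, li = layer_bounds(check_layer(layer))
    gaps = seg.boundary_rows[li] - seg.boundary_rows[ui]
    return float(np.mean(gaps) * axial_pitch)


def total_retina_thickness(seg: LayerSegmentation, axial_pitch: float) -> float:
    """Mean vitreous/RNFL-to-RPE/choroid distance in microns.

    Equals the sum of the seven layer thicknesses exactly (shared-boundary
    convention).
    """
    gaps = seg.boundary_rows[-1] - seg.boundary_rows[0]
    return float(np.mean(gaps) * axial_pitch)


def _layer_pixel_mean(
    image: BScan, seg: LayerSegmentation, layer: str, keep: np.ndarray
) -> tuple[float, int]:
    """Mean intensity of the layer band over the kept A-scans."""
    ui, li = layer_bounds(layer)
    top = np.ceil(seg.boundary_rows[ui]).astype(int)
    bot = np.ceil(seg.boundary_rows[li]).astype(int)
    total, count = 0.0, 0
    for c in np.flatnonzero(keep):
        if bot[c] > top[c]:
            total += float(image.pixels[top[c]:bot[c], c].sum())
            count += bot[c] - top[c]
    return (total / count if count else np.nan), count


def layer_reflectivity(
    image: BScan,
    seg: LayerSegmentation,
    mask: ShadowMask | None,
    layer: str,
) -> float:
    """Mean layer intensity normalized to the RPE mean, shadow columns excluded.

    Dimensionless; 1.0 for the RPE itself by construction, and invariant to
    multiplying the whole image by any positive constant.
    """
    check_layer(layer)
    keep = ~mask.column_mask() if mask is not None else np.ones(image.n_ascans, bool)
    if not keep.any():
        raise ValueError("all A-scans masked; reflectivity undefined")
    rpe_mean, rpe_count = _layer_pixel_mean(image, seg, "RPE", keep)
    if rpe_count == 0 or not np.isfinite(rpe_mean) or rpe_mean == 0:
        raise ValueError("degenerate reference: RPE band empty or zero-intensity")
    layer_mean, count = _layer_pixel_mean(image, seg, layer, keep)
    if count == 0:
        return float("nan")
    return float(layer_mean / rpe_mean)
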