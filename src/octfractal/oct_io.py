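"""Containers and file I/O for B-scans, segmentations, masks and features.

Coordinate convention (fixed package-wide): a B-scan is a 2-D array with
rows = depth (row 0 on the vitreous side) and columns = lateral A-scan
index, 0-based.  Boundary rows are real-valued (sub-pixel); a layer
occupies the half-open depth interval [upper boundary, lower boundary)
so shared boundaries are never double counted.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .layers import BOUNDARIES, LAYERS, check_layer, layer_bounds

logger = logging.getLogger(__name__)

GROUP_HEALTHY = "healthy"
GROUP_DISEASED = "MDR"

#: Feature names used in StudyTable columns, as ``{feature}_{layer}``.
FEATURES = ("thickness", "fd", "reflectivity")


@dataclasses.dataclass
class BScan:
    """One OCT cross-sectional intensity image.

    Parameters
    ----------
    pixels : ndarray, shape (n_depth, n_ascans)
        Non-negative intensities; row 0 is the vitreous side.
    axial_pitch : float
        Microns per depth pixel.
    lateral_pitch : float
        Microns per A-scan.
    """

    pixels: np.ndarray
    axial_pitch: float
    lateral_pitch: float
    scan_id: str = ""
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("BScan requires a non-empty 2-D intensity matrix")
        if np.nanmin(self.pixels) < 0:
            raise ValueError("BScan intensities must be non-negative")
        if self.axial_pitch <= 0 or self.lateral_pitch <= 0:
            raise ValueError("pixel pitches must be positive")

    @property
    def n_depth(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_ascans(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class LayerSegmentation:
    """Per-A-scan depth positions of the 8 boundaries (fractional pixels).

    ``boundary_rows`` has shape (8, n_ascans) in the fixed anatomical order
    of :data:`octfractal.layers.BOUNDARIES`.
    """

    boundary_rows: np.ndarray

    def __post_init__(self) -> None:
        self.boundary_rows = np.asarray(self.boundary_rows, dtype=float)
        if self.boundary_rows.ndim != 2 or self.boundary_rows.shape[0] != len(BOUNDARIES):
            raise ValueError(
                f"boundary_rows must be ({len(BOUNDARIES)}, n_ascans); "
                f"got {self.boundary_rows.shape}"
            )

    @property
    def n_ascans(self) -> int:
        return self.boundary_rows.shape[1]

    def upper(self, layer: str) -> np.ndarray:
        """Row of the boundary on the vitreous side of ``layer``."""
        return self.boundary_rows[layer_bounds(check_layer(layer))[0]]

    def lower(self, layer: str) -> np.ndarray:
        """Row of the boundary on the choroid side of ``layer``."""
        return self.boundary_rows[layer_bounds(check_layer(layer))[1]]

    def validate(self, n_depth: int | None = None) -> None:
        """Raise ValueError on boundary crossings or out-of-range rows."""
        diffs = np.diff(self.boundary_rows, axis=0)
        bad = np.where((diffs < 0).any(axis=0))[0]
        if bad.size:
            raise ValueError(
                "boundary crossing (non-monotone order) at A-scans "
                f"{bad.tolist()[:20]}{'...' if bad.size > 20 else ''}"
            )
        if np.any(self.boundary_rows < 0):
            raise ValueError("negative boundary rows")
        if n_depth is not None and np.any(self.boundary_rows > n_depth):
            raise ValueError("boundary rows exceed image depth")


# ---------------------------------------------------------------------------
# B-scan readers / writers
# ---------------------------------------------------------------------------

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


def read_bscan(
    path: str | Path,
    axial_pitch: float,
    lateral_pitch: float,
    scan_id: str = "",
    eye_id: str = "",
) -> BScan:
    """Read a grayscale TIFF/PNG or whitespace-delimited text matrix.

    Color images are rejected: intensity analysis is defined on a single
    reflectivity channel only.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    elif suffix == ".png":
        from PIL import Image

        with Image.open(path) as im:
            if im.mode not in ("L", "I", "I;16", "F"):
                raise ValueError(
                    f"{path.name}: color/multichannel PNG (mode {im.mode}) "
                    "not supported; grayscale only"
                )
            arr = np.asarray(im)
    else:
        try:
            arr = np.loadtxt(path, dtype=float)
        except ValueError as exc:
            raise ValueError(f"{path.name}: unreadable numeric text matrix: {exc}") from exc
    arr = np.atleast_2d(arr)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{path.name}: empty image")
    return BScan(
        pixels=arr.astype(float),
        axial_pitch=axial_pitch,
        lateral_pitch=lateral_pitch,
        scan_id=scan_id or path.stem,
        eye_id=eye_id,
    )


def write_bscan(bscan: BScan, path: str | Path) -> None:
    """Write a B-scan as 16-bit grayscale TIFF/PNG (or a text matrix).

    Integer-valued pixel data in [0, 65535] is stored exactly, so
    ``read_bscan(write_bscan(x))`` round-trips bit-identically for
    quantized images.  Float data is scaled by 65535 / max.
    """
    path = Path(path)
    px = bscan.pixels
    if np.issubdtype(px.dtype, np.integer) or np.all(px == np.round(px)):
        if px.max() > 65535:
            raise ValueError("integer pixel values exceed 16-bit range")
        data = px.astype(np.uint16)
    else:
        top = float(px.max())
        scale = 65535.0 / top if top > 0 else 1.0
        data = np.round(px * scale).astype(np.uint16)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, data)
    elif suffix == ".png":
        from PIL import Image

        Image.fromarray(data.astype(np.uint32), mode="I").convert("I;16").save(path)
    else:
        np.savetxt(path, data, fmt="%d")


def quantize_bscan(bscan: BScan, max_intensity: float = 2.0) -> BScan:
    """Return a copy with intensities quantized to integers in [0, 65535].

    ``max_intensity`` maps to 65535; values above it saturate.  Useful for
    exact round-trips through 16-bit files.
    """
    data = np.clip(bscan.pixels / max_intensity, 0.0, 1.0)
    return dataclasses.replace(bscan, pixels=np.round(data * 65535.0))


# ---------------------------------------------------------------------------
# Segmentation tables
# ---------------------------------------------------------------------------


def segmentation_to_frame(seg: LayerSegmentation, scan_id: str) -> pd.DataFrame:
    """Long-format boundary table (scan_id, ascan_index, boundary_name, depth_row)."""
    n = seg.n_ascans
    return pd.DataFrame(
        {
            "scan_id": np.repeat(scan_id, n * len(BOUNDARIES)),
            "ascan_index": np.tile(np.arange(n), len(BOUNDARIES)),
            "boundary_name": np.repeat(list(BOUNDARIES), n),
            "depth_row": seg.boundary_rows.ravel(),
        }
    )


def write_segmentation(seg: LayerSegmentation, path: str | Path, scan_id: str) -> None:
    segmentation_to_frame(seg, scan_id).to_csv(path, index=False, float_format="%.10g")


def read_segmentation(
    path_or_frame: str | Path | pd.DataFrame,
    bscan: BScan,
    scan_id: str | None = None,
) -> LayerSegmentation:
    """Read a long-format boundary CSV into a dense per-A-scan table.

    A-scans missing from the table are filled by linear interpolation from
    their neighbours (interior gaps only; gaps touching the image edge are
    rejected).  Monotonicity of the boundary order is enforced.
    """
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame)
    required = {"scan_id", "ascan_index", "boundary_name", "depth_row"}
    if not required.issubset(df.columns):
        raise ValueError(f"segmentation table must have columns {sorted(required)}")
    if scan_id is None:
        scan_id = bscan.scan_id
    if scan_id:
        sub = df[df["scan_id"].astype(str) == str(scan_id)]
        if not len(sub) and df["scan_id"].nunique() == 1:
            sub = df  # single-scan file; tolerate id mismatch
    else:
        sub = df
    if not len(sub):
        raise ValueError(f"no segmentation rows for scan {scan_id!r}")
    unknown = set(sub["boundary_name"]) - set(BOUNDARIES)
    if unknown:
        raise ValueError(f"unknown boundary names: {sorted(unknown)}")

    n = bscan.n_ascans
    rows = np.full((len(BOUNDARIES), n), np.nan)
    for b, name in enumerate(BOUNDARIES):
        part = sub[sub["boundary_name"] == name]
        idx = part["ascan_index"].to_numpy(dtype=int)
        if np.any((idx < 0) | (idx >= n)):
            raise ValueError(f"{name}: A-scan indices outside [0, {n})")
        rows[b, idx] = part["depth_row"].to_numpy(dtype=float)
        missing = np.isnan(rows[b])
        if missing.any():
            if missing[0] or missing[-1]:
                raise ValueError(
                    f"{name}: missing A-scans at the image edge cannot be interpolated"
                )
            known = np.where(~missing)[0]
            rows[b, missing] = np.interp(np.where(missing)[0], known, rows[b, known])
            logger.info(
                "segmentation %s/%s: interpolated %d missing A-scans",
                scan_id, name, int(missing.sum()),
            )
    seg = LayerSegmentation(rows)
    seg.validate(n_depth=bscan.n_depth)
    return seg


# ---------------------------------------------------------------------------
# Study / feature tables
# ---------------------------------------------------------------------------


def feature_column(feature: str, layer: str) -> str:
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    return f"{feature}_{check_layer(layer)}"


def study_columns() -> list[str]:
    """Stable column order of a StudyTable CSV."""
    return ["eye_id", "group"] + [feature_column(f, l) for f in FEATURES for l in LAYERS]


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write an eye-level feature table with a stable column order.

    Numeric values keep >= 10 significant digits so that cutoff-scale
    quantities survive a round-trip unchanged.
    """
    cols = [c for c in study_columns() if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False, float_format="%.12g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
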