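"""Despeckling and blood-vessel shadow detection.

Blood vessels sit in the inner retina and cast dark vertical shadows down
through the outer layers of a B-scan.  Columns under a shadow carry
attenuated reflectivity and must be excluded before any intensity-based
measurement (fractal dimension, normalized reflectivity); layer boundaries
remain valid under shadows, so thickness is not affected.

Detection works on a *shadowgram*: the lateral profile of mean intensity
over the outer-retina band (OPL/ONL+IS boundary down to OS/RPE), where
shadows are darkest.  Columns falling below a robust (median/MAD) relative
threshold are grouped into vertical-edge-delimited runs and width-filtered.
The threshold is relative, so detection is invariant to a global intensity
rescaling of the image.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .layers import BOUNDARY_INDEX
from .oct_io import BScan, LayerSegmentation


@dataclasses.dataclass
class ShadowMask:
    """Lateral A-scan intervals excluded as blood-vessel shadows.

    ``intervals`` are half-open ``(start, stop)`` column ranges;
    ``excluded_columns`` is their union.
    """

    intervals: list[tuple[int, int]]
    n_ascans: int
    method_params: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for start, stop in self.intervals:
            if not (0 <= start < stop <= self.n_ascans):
                raise ValueError(f"interval ({start}, {stop}) outside [0, {self.n_ascans})")

    @classmethod
    def empty(cls, n_ascans: int) -> "ShadowMask":
        return cls(intervals=[], n_ascans=n_ascans)

    @property
    def excluded_columns(self) -> set[int]:
        cols: set[int] = set()
        for start, stop in self.intervals:
            cols.update(range(start, stop))
        return cols

    def column_mask(self) -> np.ndarray:
        """Boolean vector, True where the A-scan is excluded."""
        mask = np.zeros(self.n_ascans, dtype=bool)
        for start, stop in self.intervals:
            mask[start:stop] = True
        return mask

    def to_frame(self, scan_id: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scan_id": scan_id,
                "ascan_index": np.arange(self.n_ascans),
                "excluded": self.column_mask().astype(int),
            }
        )


def read_shadow_mask(path, n_ascans: int | None = None) -> ShadowMask:
    """Read a mask CSV (scan_id, ascan_index, excluded) back into intervals."""
    df = pd.read_csv(path)
    if n_ascans is None:
        n_ascans = int(df["ascan_index"].max()) + 1
    flags = np.zeros(n_ascans, dtype=bool)
    flagged = df.loc[df["excluded"] > 0, "ascan_index"].to_numpy(dtype=int)
    flags[flagged] = True
    return ShadowMask(intervals=_runs(flags), n_ascans=n_ascans)


def despeckle(image: BScan, window: int = 3) -> BScan:
    """2-D median filter with an odd square window; window 1 is the identity."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    if window == 1:
        return image
    return dataclasses.replace(image, pixels=median_filter(image.pixels, size=window))


def shadowgram_profile(image: BScan, seg: LayerSegmentation) -> np.ndarray:
    """Mean outer-retina intensity per A-scan (NaN where the band is empty).

    The band runs from the OPL/ONL+IS boundary down to (excluding) OS/RPE,
    i.e. the photoreceptor complex where vessel shadows are most pronounced.
    """
    top_rows = seg.boundary_rows[BOUNDARY_INDEX["OPL/ONL+IS"]]
    bot_rows = seg.boundary_rows[BOUNDARY_INDEX["OS/RPE"]]
    n = image.n_ascans
    profile = np.full(n, np.nan)
    top = np.ceil(top_rows).astype(int)
    bot = np.ceil(bot_rows).astype(int)
    for c in range(n):
        if bot[c] > top[c]:
            profile[c] = image.pixels[top[c]:bot[c], c].mean()
    return profile


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) runs of True."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), stops.tolist()))


def _refine_edges(
    start: int, stop: int, deriv: np.ndarray, limit: int = 1
) -> tuple[int, int]:
    """Trim run edges to the lateral-derivative sign change.

    Vessel shadows have vertical walls, so the shadowgram falls steeply
    (negative derivative) into the left edge and rises (positive) out of
    the right.  A boundary column whose derivative does not match the
    expected wall sign is shaved off (at most ``limit`` columns per side);
    runs are never extended beyond the thresholded columns, which keeps
    the per-column false-positive rate down.
    """
    left, right = start, stop
    for _ in range(limit):
        if right - left > 1 and deriv[left] >= 0:
            left += 1
        if right - left > 1 and deriv[right - 1] <= 0:
            right -= 1
    return left, right


def detect_shadows(
    image: BScan,
    seg: LayerSegmentation,
    k_sigma: float = 2.0,
    min_width: int = 3,
    max_width: int = 40,
) -> ShadowMask:
    """Detect vertical blood-vessel shadow columns in a B-scan.

    Columns whose shadowgram value falls below
    ``median - k_sigma * (1.4826 * MAD)`` are candidates; consecutive
    candidates form runs whose edges are refined by the sign changes of the
    lateral first derivative (central differences); runs separated by a
    single clean column are merged; runs with width outside
    ``[min_width, max_width]`` are discarded.
    """
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    if not (1 <= min_width <= max_width):
        raise ValueError("need 1 <= min_width <= max_width")
    profile = shadowgram_profile(image, seg)
    finite = np.isfinite(profile)
    if not finite.any():
        raise ValueError("shadowgram undefined: outer-retina band empty everywhere")
    med = np.median(profile[finite])
    mad = np.median(np.abs(profile[finite] - med))
    threshold = med - k_sigma * 1.4826 * mad
    flags = finite & (profile < threshold)

    if flags.sum() > 0.5 * image.n_ascans:
        raise ValueError(
            "threshold implausible: more than half of all columns flagged as shadow"
        )

    deriv = np.gradient(np.where(finite, profile, med))
    runs = [_refine_edges(s, e, deriv) for s, e in _runs(flags)]

    # merge runs separated by a single non-flagged column
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= 1:
            merged[-1] = (merged[-1][0], max(run[1], merged[-1][1]))
        else:
            merged.append(run)
    kept = [(s, e) for s, e in merged if min_width <= e - s <= max_width]
    return ShadowMask(
        intervals=kept,
        n_ascans=image.n_ascans,
        method_params={
            "k_sigma": k_sigma,
            "min_width": min_width,
            "max_width": max_width,
            "threshold": float(threshold),
        },
    )
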