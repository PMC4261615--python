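"""Power-spectrum fractal dimension of depth reflectivity profiles.

For each A-scan, the reflectivity profile within one intraretinal layer is
treated as a 1-D rough signal.  Its periodogram follows a power law
P(omega) ~ omega^(-beta); in log-log coordinates an ordinary least-squares
line fit gives the spectral exponent beta as minus the slope, and the
fractal dimension of the profile is

    FD = (5 - beta) / 2,

the standard relation for 1-D fractional-Brownian-type signals (beta in
(1, 3) maps onto FD in (1, 2); rougher profiles give smaller beta, larger
FD).  Per-A-scan estimates are averaged per layer per scan, and per-scan
means are averaged per eye across the radial scans.

Numerical choices: profiles are taken from ceil(upper boundary) up to but
excluding ceil(lower boundary); profiles shorter than ``min_profile``
(default 8 px) are excluded, never zero-padded; the mean is always removed
before the transform, and an optional *linear* detrend (default off) is
available for profiles with a strong boundary-to-boundary intensity ramp —
it is off by default because removing a fitted line also removes genuine
low-frequency fractal power and measurably flattens the recovered slope
on fractional-Brownian benchmarks; estimates with FD outside [0.5, 2.5]
are flagged invalid and excluded from means rather than clamped, which
would bias group means.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

from .layers import check_layer, layer_bounds
from .oct_io import BScan, LayerSegmentation
from .preprocess import ShadowMask

#: Estimates with FD outside this range are flagged invalid.
FD_VALID_RANGE = (0.5, 2.5)
MIN_FIT_POINTS = 4
DEFAULT_MIN_PROFILE = 8


@dataclasses.dataclass
class ReflectivityProfile:
    """Intensities along depth within one layer at one A-scan."""

    values: np.ndarray
    ascan_index: int
    layer: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclasses.dataclass
class PowerSpectrum:
    """One-sided periodogram: positive-frequency bins below Nyquist."""

    frequencies: np.ndarray  # cycles / pixel
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if len(self.frequencies) != len(self.power):
            raise ValueError("frequency and power vectors must have equal length")
        if np.any(self.frequencies <= 0):
            raise ValueError("DC / non-positive frequency bins must be excluded")


@dataclasses.dataclass
class FdEstimate:
    """Fitted spectral exponent and fractal dimension for one profile."""

    beta: float
    fd: float
    r_squared: float
    n_fit_points: int
    valid: bool
    reason: str = ""

    @classmethod
    def invalid(cls, reason: str) -> "FdEstimate":
        return cls(np.nan, np.nan, np.nan, 0, False, reason)


@dataclasses.dataclass
class LayerFdSummary:
    """Per-layer FD aggregated over the A-scans of one scan."""

    layer: str
    scan_id: str
    mean_fd: float                 # NaN when no valid A-scan
    mean_beta: float
    n_used: int
    exclusion_counts: dict[str, int]
    reason: str = ""
    per_ascan: pd.DataFrame | None = None

    @property
    def n_excluded(self) -> int:
        return sum(self.exclusion_counts.values())


def extract_profile(
    image: BScan, seg: LayerSegmentation, layer: str, ascan_index: int
) -> ReflectivityProfile:
    """Depth profile of ``layer`` at one A-scan.

    Pixels from ceil(upper boundary row) up to but excluding
    ceil(lower boundary row); a zero-height band yields an empty profile.
    """
    check_layer(layer)
    if not (0 <= ascan_index < image.n_ascans):
        raise ValueError(f"A-scan index {ascan_index} outside [0, {image.n_ascans})")
    ui, li = layer_bounds(layer)
    top = int(np.ceil(seg.boundary_rows[ui, ascan_index]))
    bot = int(np.ceil(seg.boundary_rows[li, ascan_index]))
    values = image.pixels[top:bot, ascan_index] if bot > top else np.empty(0)
    return ReflectivityProfile(values=values, ascan_index=ascan_index, layer=layer)


def power_spectrum(
    profile: ReflectivityProfile | np.ndarray,
    detrend: bool = False,
    taper: bool = False,
    min_profile: int = DEFAULT_MIN_PROFILE,
) -> PowerSpectrum:
    """Periodogram of a profile: |FFT|^2 / n over positive bins below Nyquist.

    The mean is always removed; optional linear detrend and Hann cosine
    taper (both default off).  Frequencies are k/n cycles per pixel for
    bin index k.
    """
    x = profile.values if isinstance(profile, ReflectivityProfile) else np.asarray(profile, float)
    n = len(x)
    if n < min_profile:
        raise ValueError(f"profile too short: n={n} < minimum {min_profile}")
    if detrend:
        x = _linear_detrend(x, type="linear")
    else:
        x = x - x.mean()
    if taper:
        x = x * np.hanning(n)
    spec = np.abs(np.fft.rfft(x)) ** 2 / n
    # positive bins strictly below Nyquist: k = 1 .. ceil(n/2) - 1
    k_max = (n + 1) // 2
    k = np.arange(1, k_max)
    return PowerSpectrum(frequencies=k / n, power=spec[1:k_max])


def fit_beta(spectrum: PowerSpectrum) -> FdEstimate:
    """Least-squares line in log-log coordinates: beta = -slope, FD = (5-beta)/2.

    Zero-power bins are dropped (their log is undefined); fewer than
    ``MIN_FIT_POINTS`` usable bins, or an FD outside ``FD_VALID_RANGE``,
    yields an invalid (never clamped) estimate.
    """
    keep = spectrum.power > 0
    n_pts = int(keep.sum())
    if n_pts < MIN_FIT_POINTS:
        return FdEstimate.invalid(f"only {n_pts} positive-power bins (< {MIN_FIT_POINTS})")
    logf = np.log(spectrum.frequencies[keep])
    logp = np.log(spectrum.power[keep])
    slope, intercept = np.polyfit(logf, logp, 1)
    resid = logp - (slope * logf + intercept)
    ss_tot = float(np.sum((logp - logp.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    beta = -float(slope)
    fd = (5.0 - beta) / 2.0
    lo, hi = FD_VALID_RANGE
    valid = lo < fd < hi  # open interval: a flat spectrum (fd = 2.5) is invalid
    return FdEstimate(
        beta=beta,
        fd=fd,
        r_squared=r2,
        n_fit_points=n_pts,
        valid=valid,
        reason="" if valid else f"fd {fd:.3f} outside [{lo}, {hi}]",
    )


def estimate_profile_fd(
    values: np.ndarray,
    detrend: bool = False,
    taper: bool = False,
    min_profile: int = DEFAULT_MIN_PROFILE,
    band: tuple[int | None, int | None] = (None, None),
) -> FdEstimate:
    """Convenience: periodogram + log-log fit for a raw 1-D profile.

    ``band`` optionally restricts the fit to bin indices [low, high) of the
    one-sided spectrum (for sensitivity analysis; default uses all bins).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < min_profile:
        return FdEstimate.invalid(f"profile too short: n={len(values)} < {min_profile}")
    spec = power_spectrum(values, detrend=detrend, taper=taper, min_profile=min_profile)
    lo, hi = band
    if lo is not None or hi is not None:
        sl = slice(lo, hi)
        spec = PowerSpectrum(spec.frequencies[sl], spec.power[sl])
    return fit_beta(spec)


def layer_fd(
    image: BScan,
    seg: LayerSegmentation,
    mask: ShadowMask | None,
    layer: str,
    detrend: bool = False,
    taper: bool = False,
    min_profile: int = DEFAULT_MIN_PROFILE,
    band: tuple[int | None, int | None] = (None, None),
    keep_per_ascan: bool = False,
) -> LayerFdSummary:
    """Mean FD of one layer over all non-masked A-scans of a scan.

    Every A-scan is accounted for: it contributes to the mean or is counted
    under one exclusion cause (``masked``, ``too_short``, ``invalid_fit``).
    """
    check_layer(layer)
    excluded = mask.column_mask() if mask is not None else np.zeros(image.n_ascans, bool)
    counts = {"masked": 0, "too_short": 0, "invalid_fit": 0}
    fds, betas, records = [], [], []
    for c in range(image.n_ascans):
        if excluded[c]:
            counts["masked"] += 1
            rec = ("masked", np.nan, np.nan, np.nan)
        else:
            profile = extract_profile(image, seg, layer, c)
            est = estimate_profile_fd(
                profile.values, detrend=detrend, taper=taper,
                min_profile=min_profile, band=band,
            )
            if not est.valid:
                cause = "too_short" if "short" in est.reason else "invalid_fit"
                counts[cause] += 1
                rec = (cause, est.beta, est.fd, est.r_squared)
            else:
                fds.append(est.fd)
                betas.append(est.beta)
                rec = ("", est.beta, est.fd, est.r_squared)
        if keep_per_ascan:
            records.append(
                {"scan_id": image.scan_id, "ascan_index": c, "layer": layer,
                 "exclusion_reason": rec[0], "beta": rec[1], "fd": rec[2],
                 "r_squared": rec[3], "valid": rec[0] == ""}
            )
    per_ascan = pd.DataFrame(records) if keep_per_ascan else None
    if fds:
        return LayerFdSummary(
            layer=layer, scan_id=image.scan_id,
            mean_fd=float(np.mean(fds)), mean_beta=float(np.mean(betas)),
            n_used=len(fds), exclusion_counts=counts, per_ascan=per_ascan,
        )
    return LayerFdSummary(
        layer=layer, scan_id=image.scan_id, mean_fd=np.nan, mean_beta=np.nan,
        n_used=0, exclusion_counts=counts, reason="no valid A-scans",
        per_ascan=per_ascan,
    )


def eye_fd(summaries: list[LayerFdSummary]) -> float:
    """Unweighted mean of per-scan mean FDs (one layer, one eye).

    Scans with no valid A-scans are skipped; NaN when all are missing.
    """
    if not summaries:
        raise ValueError("need at least one per-scan summary")
    layers = {s.layer for s in summaries}
    if len(layers) != 1:
        raise ValueError(f"summaries mix layers: {sorted(layers)}")
    vals = [s.mean_fd for s in summaries if np.isfinite(s.mean_fd)]
    return float(np.mean(vals)) if vals else float("nan")
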