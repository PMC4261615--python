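"""Synthetic retinal B-scan phantoms with known ground truth.

The phantom emulates the geometry of a time-domain macular line scan:
seven intraretinal layers between eight smooth boundaries with a Gaussian
foveal pit, per-layer mean reflectivity, per-layer depth texture with a
planted spectral exponent beta (so the fractal dimension FD = (5 - beta)/2
is known exactly), unit-mean multiplicative gamma speckle, and vertical
blood-vessel shadow columns.  Every downstream stage of the pipeline can
therefore be validated against planted truth.

Texture is synthesised per A-scan as a 1-D signal along depth whose
expected power spectrum decays as omega^(-beta) (fractional-Brownian-style
spectral shaping: independent Gaussian Fourier coefficients with magnitude
proportional to omega^(-beta/2)).  The texture is planted in exactly the
direction the estimator measures.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from .layers import BOUNDARIES, INNER_LAYERS, LAYERS
from .oct_io import BScan, LayerSegmentation
from .preprocess import ShadowMask

logger = logging.getLogger(__name__)

#: Healthy-macula per-layer defaults: mean thickness (um) and fractal
#: dimension of the depth reflectivity texture.  The spectral exponent is
#: derived as beta = 5 - 2 FD.
DEFAULT_THICKNESS_UM: dict[str, float] = {
    "RNFL": 42.02,
    "GCL+IPL": 78.30,
    "INL": 35.02,
    "OPL": 41.30,
    "ONL+IS": 86.41,
    "OS": 16.27,
    "RPE": 12.71,
}
DEFAULT_FD: dict[str, float] = {
    "RNFL": 1.74,
    "GCL+IPL": 1.68,
    "INL": 1.78,
    "OPL": 1.51,
    "ONL+IS": 1.78,
    "OS": 1.70,
    "RPE": 1.68,
}
DEFAULT_REFLECTIVITY: dict[str, float] = {
    "RNFL": 0.55,
    "GCL+IPL": 0.32,
    "INL": 0.28,
    "OPL": 0.38,
    "ONL+IS": 0.18,
    "OS": 0.40,
    "RPE": 0.85,
}

BACKGROUND_REFLECTIVITY = 0.02


def beta_from_fd(fd: float | np.ndarray) -> float | np.ndarray:
    """Spectral exponent of a 1-D profile with fractal dimension ``fd``."""
    return 5.0 - 2.0 * np.asarray(fd, dtype=float)


def fd_from_beta(beta: float | np.ndarray) -> float | np.ndarray:
    """Fractal dimension of a 1-D profile with spectral exponent ``beta``."""
    return (5.0 - np.asarray(beta, dtype=float)) / 2.0


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic B-scan.

    All per-layer sequences follow the fixed order of
    :data:`octfractal.layers.LAYERS`.  ``layer_beta`` must lie in (1, 3),
    i.e. FD in (1, 2).  ``speckle_looks`` is the shape of the unit-mean
    gamma multiplicative noise; ``None`` (or inf) disables speckle.
    """

    n_ascans: int = 512
    n_depth: int = 1024
    axial_pitch: float = 2.0     # um per depth pixel
    lateral_pitch: float = 11.7  # um per A-scan (6 mm / 512)
    layer_mean_thickness: tuple[float, ...] = tuple(
        DEFAULT_THICKNESS_UM[l] for l in LAYERS
    )
    layer_reflectivity: tuple[float, ...] = tuple(
        DEFAULT_REFLECTIVITY[l] for l in LAYERS
    )
    layer_beta: tuple[float, ...] = tuple(
        float(beta_from_fd(DEFAULT_FD[l])) for l in LAYERS
    )
    foveal_pit_depth: float = 110.0   # um of inner-retina thinning at centre
    foveal_pit_width: float = 600.0   # Gaussian sigma, um lateral
    texture_amplitude: float = 0.35   # relative RMS of the depth texture
    speckle_looks: float | None = 1000.0
    shadow_columns: tuple[tuple[int, int], ...] = ()  # (start, width)
    shadow_attenuation: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_ascans < 1 or self.n_depth < 1:
            raise ValueError("n_ascans and n_depth must be positive")
        arrs = {
            "layer_mean_thickness": self.layer_mean_thickness,
            "layer_reflectivity": self.layer_reflectivity,
            "layer_beta": self.layer_beta,
        }
        for name, seq in arrs.items():
            if len(seq) != len(LAYERS):
                raise ValueError(f"{name} must have {len(LAYERS)} entries")
        if not all(0.0 <= r <= 1.0 for r in self.layer_reflectivity):
            raise ValueError("layer reflectivities must lie in [0, 1]")
        if not all(1.0 < b < 3.0 for b in self.layer_beta):
            raise ValueError("layer_beta values must lie in (1, 3)")
        if not (0.0 < self.shadow_attenuation < 1.0) and self.shadow_columns:
            raise ValueError("shadow_attenuation must lie in (0, 1)")
        if self.texture_amplitude < 0:
            raise ValueError("texture_amplitude must be non-negative")
        if self.speckle_looks is not None and self.speckle_looks <= 0:
            raise ValueError("speckle_looks must be positive (or None)")
        total = sum(self.layer_mean_thickness)
        margin = 2 * _MARGIN_PX * self.axial_pitch
        if total + margin > self.n_depth * self.axial_pitch:
            raise ValueError(
                f"layers do not fit: {total:.1f} um of retina + {margin:.1f} um "
                f"margins exceed the {self.n_depth * self.axial_pitch:.1f} um "
                "imaging depth"
            )
        for start, width in self.shadow_columns:
            if width < 1 or start < 0 or start + width > self.n_ascans:
                raise ValueError(f"shadow interval ({start}, {width}) outside image")

    @property
    def layer_fd(self) -> np.ndarray:
        return np.asarray(fd_from_beta(np.asarray(self.layer_beta)))


@dataclasses.dataclass
class PhantomTruth:
    """Ground truth attached to one generated B-scan."""

    boundaries: LayerSegmentation
    shadow_columns: ShadowMask
    layer_beta: np.ndarray
    layer_fd: np.ndarray

    def __post_init__(self) -> None:
        expected = fd_from_beta(self.layer_beta)
        if not np.allclose(self.layer_fd, expected, rtol=0, atol=0):
            raise ValueError("layer_fd must equal (5 - beta)/2 exactly")


_MARGIN_PX = 8  # minimum clear rows above / below the retina


def spectral_texture(
    n: int, beta: float, n_cols: int, rng: np.random.Generator
) -> np.ndarray:
    """Zero-mean, unit-variance 1-D textures with power spectrum ~ omega^-beta.

    Returns an (n, n_cols) array; each column is an independent realisation
    synthesised from Gaussian Fourier coefficients with magnitudes
    proportional to k^(-beta/2), so the expected periodogram decays exactly
    as a power law in the frequency index.
    """
    if n < 2:
        return np.zeros((n, n_cols))
    k = np.arange(1, n // 2 + 1, dtype=float)
    mag = k ** (-beta / 2.0)
    re = rng.standard_normal((len(k), n_cols))
    im = rng.standard_normal((len(k), n_cols))
    coef = (re + 1j * im) * mag[:, None]
    if n % 2 == 0:
        coef[-1] = coef[-1].real  # Nyquist coefficient must be real
    spec = np.concatenate([np.zeros((1, n_cols), dtype=complex), coef], axis=0)
    x = np.fft.irfft(spec, n=n, axis=0)
    x -= x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _build_boundaries(spec: PhantomSpec) -> np.ndarray:
    """Smooth boundary rows (8, n_ascans) with a Gaussian foveal pit.

    The outer retinal surface (RPE/choroid) is flat; the inner layers thin
    toward the lateral centre so the inner surface dips, as in a macular
    line scan through the fovea.
    """
    n = spec.n_ascans
    x_um = (np.arange(n) - (n - 1) / 2.0) * spec.lateral_pitch
    pit = np.exp(-0.5 * (x_um / spec.foveal_pit_width) ** 2)

    thickness = np.tile(
        np.asarray(spec.layer_mean_thickness, dtype=float)[:, None], (1, n)
    )
    inner_idx = [LAYERS.index(l) for l in INNER_LAYERS]
    inner_total = thickness[inner_idx, :].sum(axis=0)
    # cap pit depth so no layer collapses below 5% of its nominal thickness
    depth = np.minimum(spec.foveal_pit_depth, 0.95 * inner_total.min())
    shrink = 1.0 - depth * pit / np.maximum(inner_total, 1e-9)
    thickness[inner_idx, :] *= shrink

    bottom_um = (spec.n_depth - _MARGIN_PX) * spec.axial_pitch
    rows_um = np.empty((len(BOUNDARIES), n))
    rows_um[-1] = bottom_um
    for b in range(len(LAYERS) - 1, -1, -1):
        rows_um[b] = rows_um[b + 1] - thickness[b]
    if rows_um[0].min() < _MARGIN_PX * spec.axial_pitch:
        raise ValueError("layers do not fit in the imaging depth")
    return rows_um / spec.axial_pitch


def generate_bscan(
    spec: PhantomSpec,
    scan_id: str = "phantom",
    eye_id: str = "",
    rng: np.random.Generator | None = None,
) -> tuple[BScan, PhantomTruth]:
    """Generate one synthetic B-scan plus its ground truth.

    Identical spec and seed reproduce byte-identical images.
    """
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    rows = _build_boundaries(spec)
    seg = LayerSegmentation(rows)
    seg.validate(n_depth=spec.n_depth)

    img = np.full((spec.n_depth, spec.n_ascans), BACKGROUND_REFLECTIVITY)
    for li, layer in enumerate(LAYERS):
        top = np.ceil(rows[li]).astype(int)
        bot = np.ceil(rows[li + 1]).astype(int)
        heights = bot - top
        refl = spec.layer_reflectivity[li]
        beta = spec.layer_beta[li]
        # batch columns sharing a band height so each profile gets a
        # texture of exactly its own length
        for h in np.unique(heights):
            cols = np.where(heights == h)[0]
            if h <= 0:
                continue
            tex = spectral_texture(int(h), beta, len(cols), rng)
            band = refl * (1.0 + spec.texture_amplitude * tex)
            for j, c in enumerate(cols):
                img[top[c]:bot[c], c] = band[:, j]

    if spec.speckle_looks is not None and math.isfinite(spec.speckle_looks):
        looks = float(spec.speckle_looks)
        img *= rng.gamma(shape=looks, scale=1.0 / looks, size=img.shape)

    intervals = [(int(s), int(s + w)) for s, w in spec.shadow_columns]
    inner_top = np.ceil(rows[0]).astype(int)
    for start, stop in intervals:
        for c in range(start, stop):
            img[inner_top[c]:, c] *= spec.shadow_attenuation

    img = np.clip(img, 0.0, None)
    mask = ShadowMask(
        intervals=intervals,
        n_ascans=spec.n_ascans,
        method_params={"source": "planted"},
    )
    truth = PhantomTruth(
        boundaries=seg,
        shadow_columns=mask,
        layer_beta=np.asarray(spec.layer_beta, dtype=float),
        layer_fd=np.asarray(fd_from_beta(np.asarray(spec.layer_beta))),
    )
    bscan = BScan(
        pixels=img,
        axial_pitch=spec.axial_pitch,
        lateral_pitch=spec.lateral_pitch,
        scan_id=scan_id,
        eye_id=eye_id,
    )
    return bscan, truth


def make_eye(
    spec: PhantomSpec, n_scans: int = 6, eye_id: str = "eye"
) -> list[tuple[BScan, PhantomTruth]]:
    """Generate ``n_scans`` independent replicate B-scans of one eye.

    All scans share the layer parameters (the per-eye truth); their
    realisations differ.  Scan seeds derive deterministically from
    ``spec.seed`` and the scan index via a spawned seed sequence.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    out = []
    for i in range(n_scans):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(i,)))
        out.append(
            generate_bscan(spec, scan_id=f"{eye_id}_scan{i}", eye_id=eye_id, rng=rng)
        )
    return out


@dataclasses.dataclass
class CohortTruth:
    """Eye-level metadata and ground-truth parameters of a phantom study."""

    table: "pd.DataFrame"  # eye_id, group, true per-layer fd / thickness
    specs: dict[str, PhantomSpec]
    n_resampled: int = 0


def _as_per_layer(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(len(LAYERS), float(arr))
    if arr.shape != (len(LAYERS),):
        raise ValueError(f"{name} must be a scalar or one value per layer")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0")
    return arr


def make_cohort(
    healthy_spec: PhantomSpec,
    diseased_spec: PhantomSpec,
    n_healthy: int,
    n_diseased: int,
    between_eye_fd_sd,
    between_eye_thickness_sd=0.0,
    diseased_fd_sd=None,
    diseased_thickness_sd=None,
    seed: int | None = None,
) -> CohortTruth:
    """Draw a two-group cohort of per-eye layer parameters.

    Each eye's per-layer fractal dimension and mean thickness are jittered
    around its group spec by normal deviates with the given between-eye SDs
    (scalar or per layer; the diseased group may get its own SDs).  Draws
    that leave the valid domain (FD outside (1, 2), thickness <= 0) are
    resampled and counted.  The returned table carries the eye-level truth
    the stats module consumes; ``specs`` holds a ready-to-render
    :class:`PhantomSpec` per eye.
    """
    import pandas as pd

    if n_healthy < 2 or n_diseased < 2:
        raise ValueError("each group needs at least 2 eyes")
    fd_sd_h = _as_per_layer(between_eye_fd_sd, "between_eye_fd_sd")
    th_sd_h = _as_per_layer(between_eye_thickness_sd, "between_eye_thickness_sd")
    fd_sd_d = fd_sd_h if diseased_fd_sd is None else _as_per_layer(diseased_fd_sd, "diseased_fd_sd")
    th_sd_d = th_sd_h if diseased_thickness_sd is None else _as_per_layer(
        diseased_thickness_sd, "diseased_thickness_sd"
    )
    if seed is None:
        seed = healthy_spec.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xC0,)))

    rows = []
    specs: dict[str, PhantomSpec] = {}
    n_resampled = 0
    groups = [
        ("healthy", healthy_spec, n_healthy, fd_sd_h, th_sd_h),
        ("MDR", diseased_spec, n_diseased, fd_sd_d, th_sd_d),
    ]
    for group, gspec, count, fd_sd, th_sd in groups:
        base_fd = np.asarray(fd_from_beta(np.asarray(gspec.layer_beta)))
        base_th = np.asarray(gspec.layer_mean_thickness, dtype=float)
        for e in range(count):
            eye_id = f"{group}_{e:03d}"
            for _attempt in range(1000):
                fd = base_fd + fd_sd * rng.standard_normal(len(LAYERS))
                th = base_th + th_sd * rng.standard_normal(len(LAYERS))
                if np.all((fd > 1.0) & (fd < 2.0)) and np.all(th > 0):
                    break
                n_resampled += 1
            else:  # pragma: no cover - pathological SDs
                raise ValueError("could not draw valid eye parameters in 1000 tries")
            eye_seed = int(
                np.random.SeedSequence(seed, spawn_key=(hash(eye_id) & 0xFFFF,))
                .generate_state(1)[0] % (2**31)
            )
            specs[eye_id] = dataclasses.replace(
                gspec,
                layer_beta=tuple(float(b) for b in beta_from_fd(fd)),
                layer_mean_thickness=tuple(float(t) for t in th),
                seed=eye_seed,
            )
            row = {"eye_id": eye_id, "group": group}
            for li, layer in enumerate(LAYERS):
                row[f"true_fd_{layer}"] = fd[li]
                row[f"true_thickness_{layer}"] = th[li]
            rows.append(row)
    if n_resampled:
        logger.info("make_cohort: resampled %d out-of-domain parameter draws", n_resampled)
    return CohortTruth(table=pd.DataFrame(rows), specs=specs, n_resampled=n_resampled)
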