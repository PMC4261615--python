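# Methods

## Coordinate and layer conventions

A B-scan is a matrix with rows = depth (row 0 on the vitreous side) and
columns = lateral A-scan index.  Seven intraretinal layers (RNFL,
GCL+IPL, INL, OPL, ONL+IS, OS, RPE) are delimited by eight boundaries
given per A-scan as real-valued (sub-pixel) row positions.  A layer is
the half-open interval [upper boundary, lower boundary), so shared
boundaries are never double counted and the seven layer thicknesses sum
*exactly* to the total retinal thickness.  For pixel-based operations
(profile extraction, reflectivity) the band is `ceil(upper) .. ceil(lower)-1`;
for the geometric thickness the real-valued rows are used directly.

## Spectral fractal dimension

Within one layer at one A-scan, the depth reflectivity profile x(z) is
treated as a 1-D rough signal.  Its periodogram |FFT(x)|²/n is evaluated
on the positive-frequency bins strictly below Nyquist, and an ordinary
least-squares line is fitted to log P versus log ω over all bins with
positive power.  β is minus the slope and FD = (5 − β)/2, the standard
mapping for 1-D fractional-Brownian-type signals (an fBm with Hurst
exponent H has β = 2H + 1 and FD = 2 − H, so the two identities agree).

Numerical choices, each of which matters in practice:

* **Mean removal, not linear detrending, by default.**  Removing a
  fitted line also removes genuine low-frequency fractal power.  On
  spectral-synthesis fBm benchmarks the linear detrend inflates FD by
  ≈ +0.08 at n = 1024 for β = 2.2 and by +0.08–0.17 at layer-scale
  profile lengths (n ≈ 20–40), while mean removal is unbiased within
  Monte-Carlo error.  Linear detrending remains available
  (`detrend=True`) for real profiles with a strong boundary-to-boundary
  intensity ramp; FD is invariant to global intensity scaling either
  way, so no normalization is applied before the transform.
* **Fit band.**  All positive-power bins below Nyquist by default; an
  optional `band=(low, high)` bin cut is exposed for sensitivity
  analysis.
* **Minimum profile length 8 px.**  Shorter profiles are excluded and
  counted, never zero-padded (padding distorts the spectral slope).  At
  the default 2 µm axial pitch this excludes the OS (≈ 8 px) and RPE
  (≈ 6 px) bands from FD analysis — an honest resolution limit, reported
  as exclusions rather than hidden.
* **No clamping.**  Estimates with FD outside the open interval
  (0.5, 2.5) — e.g. the FD = 2.5 of a flat, white-noise-like spectrum —
  are flagged invalid and excluded from means; silent clamping would
  bias group means.
* **Aggregation.**  Valid per-A-scan FDs are averaged per layer per
  scan; per-scan means are averaged (unweighted) per eye across its
  replicate scans.  Every A-scan is accounted for as contributing or as
  excluded under one cause (masked / too short / invalid fit).

## Blood-vessel shadow handling

Vessels in the inner retina cast dark vertical shadows.  The detector
builds a *shadowgram* — the lateral profile of mean intensity over the
outer-retina band (OPL/ONL+IS down to OS/RPE), where shadows are
darkest — and flags columns below `median − k·(1.4826·MAD)` with
k = 2 by default.  Consecutive flagged columns form runs; run edges are
trimmed (never extended) to the sign change of the lateral central
derivative, runs separated by a single clean column are merged
(shadows are contiguous), and runs with width outside [3, 40] columns
are discarded.  The threshold is relative, so detection is invariant to
global intensity rescaling.  With the median/MAD rule at most half the
columns can ever fall below threshold; the "more than 50 % flagged"
guard is therefore purely defensive.

Shadowed columns are excluded from FD and reflectivity but *not* from
thickness: boundary positions remain valid under a shadow.  Normalized
reflectivity (layer mean ÷ RPE mean over the same columns) is itself
insensitive to a uniform column attenuation — the factor cancels in the
ratio — but masking still matters for any depth-dependent or
noise-floor-limited attenuation in real data, and raw layer intensities
are restored by masking in the phantom.

## Group statistics

One-way ANOVA per layer and feature, with significance declared at the
study's fixed p < 0.001.  Newman–Keuls is implemented as the classical
step-down studentized-range procedure: groups ordered by mean, each
pair tested at the critical value for its span r, and a pair declared
significant only when every enclosing span is (with two groups this
reduces exactly to the pooled t-test via q = t·√2).  Unequal group
sizes use the harmonic mean n, flagged in the output.

ROC analysis uses the empirical curve over all distinct thresholds; the
AUROC is the Mann–Whitney concordance computed from midranks, so tied
case–control pairs count ½.  The orientation is fixed per feature
("low calls disease" by default) and the AUROC is deliberately not
folded to ≥ 0.5, so a feature that rises with disease scores below 0.5.
The standard error is Hanley–McNeil (Q1 = A/(2−A), Q2 = 2A²/(1+A));
the 95 % CI is the asymptotic A ± 1.96·SE.  The operating cutoff is the
healthy-reference rule (healthy mean − 2·SD for features lowered by
disease, + 2·SD for raised ones) or Youden's J with ties broken toward
higher specificity; PLR = sensitivity/(1 − specificity), flagged
infinite when specificity is 1.

## The phantom: what it emulates, and what it does not

Geometry defaults follow a time-domain macular line scan: 512 A-scans
over a 6 mm transverse line (11.7 µm lateral pitch), 1024 depth pixels
at 2 µm axial pitch.  (The axial sampling is a documented convention,
not a device fact.)  Per-layer default thicknesses and fractal
dimensions are the healthy-macula reference values; β = 5 − 2·FD per
layer.  The outer surface is flat and the inner layers thin toward the
centre under a Gaussian foveal pit (plumbing realism, not anatomy).

Texture is synthesised per A-scan as a 1-D depth signal from Gaussian
Fourier coefficients with magnitudes ∝ k^(−β/2) — so the *expected*
periodogram decays exactly as k^(−β), planting truth in precisely the
direction the estimator measures — then standardised and applied as
reflectivity · (1 + 0.35 · texture).  Speckle is unit-mean gamma
multiplicative noise; the default shape (`speckle_looks = 1000`,
≈ 3 % SD) represents analysis-ready scans after frame averaging and
despeckling, which is the state in which such images are measured in
practice.  Multiplicative noise adds a white floor to the periodogram
and inflates FD at high speckle power, which is why heavy-speckle
phantoms (e.g. `speckle_looks = 4`) are used to exercise the median
despeckle filter rather than the estimator's calibration.  Shadows are
a constant multiplicative attenuation of the whole column below the
inner surface (one two-pass absorption through the vessel).

All randomness flows from a single integer seed through spawned seed
sequences (per scan, per eye), so identical specs reproduce
byte-identical images.

What the phantom does **not** model: depth-dependent signal attenuation
and roll-off, fan-beam geometry, motion artifacts, segmentation error,
macular edema or lesions, lateral correlation of tissue texture, and
detector noise floors.  Passing phantom tests therefore demonstrates
correctness of the estimators and the pipeline under known truth — not
clinical performance on device data.

## Study conditions and problem sizes

Cohort simulations use the reference two-group design (74 healthy vs 43
diseased eyes) and the GCL+IPL FD moments 1.68 ± 0.01 vs 1.58 ± 0.05,
whose closed-form binormal AUROC is Φ(0.10/√(0.01² + 0.05²)) ≈ 0.975.
The end-to-end demonstration study is deliberately desk-scale — 8–10
eyes per group, 2 replicate scans per eye, 192–256 A-scans — with
separation planted only in GCL+IPL FD, so the expected outcome is a
ranking (that row tops the comparison table), not a reproduction of
clinical effect sizes.  Estimator calibration uses n = 1024 profiles,
200 replicates per β ∈ {1.4, 1.8, 2.2}; shadow-detection operating
characteristics use 100 phantoms with randomly planted vessels.

## Known limitations

* The log-periodogram OLS estimator has per-profile SD ≈ 0.2 FD at
  layer-scale n; usable precision comes only from averaging hundreds of
  A-scans, so thin layers and heavily masked scans carry wide error.
* The FD ↔ β mapping assumes the 1-D fractional-Brownian relation; if a
  different convention is preferred only `fd_from_beta`/`beta_from_fd`
  change.
* The fixed p < 0.001 threshold is applied literally, not as a named
  multiple-comparison correction.
* The Hanley–McNeil SE is one convention among several asymptotic
  nonparametric AUROC standard errors; others differ in the third
  decimal at these sample sizes.
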