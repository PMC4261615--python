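# octfractal

Fractal-dimension, thickness and reflectivity analysis of segmented
retinal OCT B-scans, with a synthetic retinal phantom generator.

## The problem

In early diabetic retinopathy the neural retina degrades before any
clinically visible lesion appears.  Optical coherence tomography (OCT)
resolves the individual intraretinal layers, and two kinds of per-layer
measurements can pick up that early damage:

* **structure** — mean layer thickness (microns between the two
  segmented boundaries) and mean reflectivity normalized to the retinal
  pigment epithelium (RPE);
* **texture** — the *fractal dimension* (FD) of the depth reflectivity
  profile inside each layer, a roughness measure of the backscattered
  signal that changes when cellular organisation degrades.

For a 1-D profile whose power spectrum decays as a power law,
P(&omega;) &prop; &omega;<sup>&minus;&beta;</sup>, an ordinary
least-squares line in log–log coordinates gives &beta; as minus the
slope, and

&nbsp;&nbsp;&nbsp;&nbsp;FD = (5 &minus; &beta;) / 2,

the standard relation for fractional-Brownian-type signals: &beta; in
(1, 3) maps onto FD in (1, 2), rougher profiles give larger FD.  Per
A-scan estimates are averaged per layer, per scan and per eye, vessel
shadow columns are excluded first, and a two-group study is summarized
per layer and feature with one-way ANOVA (fixed p &lt; 0.001 threshold)
plus Newman–Keuls post-hoc tests, and with ROC statistics: AUROC with
Hanley–McNeil standard error and 95 % CI, an operating cutoff (healthy
mean &minus; 2 SD, or Youden), sensitivity, specificity, and the
positive likelihood ratio sensitivity/(1 &minus; specificity).

Because real clinical cohorts are rarely shareable, the package ships a
**phantom generator**: synthetic B-scans with seven layers between eight
smooth boundaries (with a foveal pit), per-layer mean reflectivity,
per-layer depth texture with a *planted* spectral exponent (so true FD
is known exactly), multiplicative gamma speckle, and vertical
blood-vessel shadows.  Every stage of the pipeline is validated against
planted truth.

## Who it is for

Researchers quantifying retinal tissue damage on segmented OCT B-scans
(boundaries supplied by any segmentation tool as CSV), and anyone who
needs a reproducible, ground-truthed test bed for 1-D spectral fractal
estimators on layered images.

## Worked example

One command generates a two-group phantom study (10 healthy vs 10
diseased eyes; the groups differ *only* in the planted GCL+IPL fractal
dimension, 1.68 &plusmn; 0.01 vs 1.58 &plusmn; 0.05) and analyzes it end
to end:

```bash
$ octfractal demo --out demo --seed 7
comparison table: demo/results/comparison.csv
highest AUROC: fd of GCL+IPL (AUROC 1.000 +- 0.000)
```

The comparison table has one row per layer &times; feature.  The planted
discriminator comes out on top (all other rows hover at AUROC &asymp;
0.5), with the recovered group means close to the planted 1.68 / 1.58:

| layer   | feature | healthy mean ± SD | diseased mean ± SD | AUROC ± SE | cutoff | PLR | p < 0.001 |
|---------|---------|-------------------|--------------------|------------|--------|-----|-----------|
| GCL+IPL | fd      | 1.691 ± 0.013     | 1.608 ± 0.039      | 1.000 ± 0.000 | 1.665 | inf | yes |

The cutoff column is the healthy-reference rule (mean &minus; 2 SD for
features lowered by disease); at that threshold sensitivity and
specificity are both 1.0 here, so the positive likelihood ratio is
flagged infinite.  ROC orientation is fixed ("low calls disease"), so a
feature that *rises* with disease scores below 0.5 instead of being
silently flipped.

The same analysis runs on real data from files: a metadata CSV
(`eye_id, group, scan_id, image_path`), grayscale TIFF/PNG B-scans, and
a boundary CSV (`scan_id, ascan_index, boundary_name, depth_row`), via
`octfractal pipeline --config config.json` or the stage-wise subcommands
(`phantom generate`, `preprocess shadows`, `fractal run`,
`morphometry run`, `stats compare`).

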