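# Methods

This note documents the models, estimators and numerical choices behind
`octa-asym`, and what the synthetic experiments do and do not establish
about real OCTA data.

## Measurement chain

An en-face angiogram is a square grayscale grid covering `field_mm`
(default 3.0 mm) at `grid_px` (default 245) pixels per side, i.e.
~12.2 µm/px, the sampling of a 245×245 A-scan macular cube. The chain:

1. **Quality gate.** Scans with device signal strength below 8 (a score
   of 7 or less) are excluded; the exclusion and its reason are recorded
   in the run manifest. A missing signal strength is an error, not a
   pass.
2. **Binarization.** Otsu's threshold by default (parameter-free and
   reproducible); a fixed threshold can be supplied instead, and must be
   for constant images, where Otsu is undefined and raises.
3. **Perfusion density.** Percent of (ROI) pixels that are vessel. An
   empty ROI raises rather than returning 0.
4. **Skeletonization and vessel density.** Zhang–Suen-type topology
   preserving thinning. Centerline length sums each 8-connected adjacency
   once: axial steps count 1 pixel size, diagonal steps √2 — a straight
   n-pixel run measures n−1 steps; an isolated pixel contributes one
   pixel size (a sub-pixel vessel fragment). Pixel counting alone would
   underestimate diagonal vessels by up to 29%, hence the √2 weighting.
   Vessel density is length per ROI area, mm⁻¹. These units are not the
   Cirrus device's internal scale; cross-device comparisons must go
   through the asymmetry index, which is invariant to any common linear
   rescaling.
5. **FAZ segmentation.** The vessel mask is morphologically closed with a
   disk of radius 2 px (bridging intercapillary gaps of up to ~4 px so
   the avascular zone does not leak into the background), then the
   4-connected avascular component containing the geometric image centre
   is taken (scans are fovea-centred). A vascular centre raises a
   no-FAZ error; a component touching the border raises an unbounded-FAZ
   error — these replace the manual adjustment step a human grader would
   perform.
6. **FAZ shape.** Area is pixel count × pixel area. The boundary is the
   marching-squares iso-contour at level 0.5, smoothed along the closed
   polygon with a circular Gaussian (σ = 1.5 contour points) before
   arc-length measurement. The smoothing matters: the raw iso-contour of
   a digitized smooth boundary carries stair-step excess that inflates
   the perimeter by ~4–5%, which squared in the circularity
   `4π·A/P²` would bias a perfect disc down to ~0.91. With smoothing,
   discs of radius 10–60 px measure area within 2%, perimeter within
   0.5% and circularity within [0.99, 1.01]. The trade-off is corner
   rounding at non-smooth boundaries: a sharp square hole reads ~0.04
   above its analytic π/4. Retinal FAZ boundaries are smooth at this
   scale, so the disc regime is the relevant one. Circularity is capped
   at 1.05 (digitization tolerance above the analytic bound of 1).
7. **Magnification correction.** Bennett-type: retinal scale is
   proportional to (axial length − 1.82 mm); measurements taken assuming
   a reference axial length (default 24.46 mm, a common device
   calibration, configurable) are rescaled by
   `f = (AL − 1.82)/(ref − 1.82)`: lengths ×f, areas ×f², vessel density
   ×1/f. Perfusion density and circularity are dimensionless fixed
   points. Correcting twice is an error. Axial lengths outside
   [20, 30] mm are rejected as biologically implausible.

## Asymmetry index

`AI = |OD − OS|/(OD + OS) × 200` (%), bounded [0, 200], zero iff the
eyes agree, symmetric under eye swap, scale-invariant. When both eyes
measure zero the AI is undefined and the package raises; cohort code maps
this to an explicit missing value, never silently to 0. No cap below 200
and no transformation is applied before statistics — the downstream
tests are rank-based precisely because AI distributions are strongly
right-skewed.

## Synthetic data

### Image level

The generator is a stand-in for a Cirrus-type device with known ground
truth, not a biophysical model. A branching random-walk process grows
strokes from border seeds toward the interior (step ~4 px, bifurcation
probability 0.18) until the vessel-pixel fraction reaches
`target_perfusion` (default 0.35); the network is a 1-px-wide mesh, which
reproduces the capillary-scale intercapillary distances (~3 px ≈ 36 µm)
that make FAZ segmentation behave as on real scans. The FAZ is imposed by
erasing vessels inside a star-convex region whose radius is modulated by
harmonics 2–5 with relative amplitude `faz_irregularity`, and is bounded
by an explicit terminal capillary ring — the anatomical arcade that
delimits the real FAZ — drawn 1 px outside the avascular zone and not
subject to dropout. Capillary dropout deletes whole branch segments
(contiguous nonperfusion patches, not salt-and-pepper noise). Gaussian
intensity noise (sd default 10 on an 8-bit scale, vessel 200 / background
40) is added last. Identical parameters and seed give bit-identical
images.

Fellow-eye pairs share base parameters; one eye — chosen by a fair coin
flip from the pair's RNG stream, so sidedness carries no signal — gets
extra dropout (`asymmetry_dropout_delta`) and/or an enlarged FAZ
(`asymmetry_faz_delta`). A 30% extra segment dropout yields a measured
perfusion drop of ~16% (segments overlap), i.e. a mean perfusion-density
AI of ~18%.

What the image generator does **not** emulate: projection artifacts,
motion artifacts, depth segmentation (the superficial/deep split is
carried as a metadata tag only), microaneurysms, edema, vessel calibre
hierarchy, or the device's proprietary density scaling. Tests passing on
these images show the measurement chain is internally correct and
recovers known ground truth; they do not certify agreement with Cirrus
outputs on clinical scans — only AI, being scale-invariant, is designed
to transfer.

### Cohort level

Repeated-cohort experiments (type-I error, power, CI coverage: 100–500
cohorts of 258 patients) cannot reasonably render ~10⁵ image pairs, so
the cohort generator draws per-eye metrics directly from the same
asymmetry model the renderer realises; a seeded consistency test checks
the two routes agree in rank on a rendered batch.

Per group g and metric m, the asymmetry index is drawn half-normal,
`AI = |N(0, τ²)|` with `τ = mean_AI(g, m)/√(2/π)`. The half-normal is
the natural model for a folded difference of two similar eyes, and its
mean/SD ratio (≈1.32) matches the strongly skewed AI summaries typical
of this setting. Default `mean_AI` values encode the study conditions: a
severity-increasing gradient with the proliferative-DR group several-fold
more asymmetric (superficial perfusion density 3.5 / 4.1 / 5.8 / 22.1%
across no DM / DM without DR / NPDR / PDR; analogous gradients for the
other six metrics). Within the diabetic groups an additive HbA1c term
`slope × (HbA1c − group mean)` (defaults: 0.5 %AI per HbA1c% on the
superficial densities, 0.8 on FAZ perimeter and circularity) injects a
known within-group slope that is orthogonal to severity, so
regression-recovery experiments have an exact truth; AI is clipped to
[0, 199].

Per-eye values are reconstructed from each drawn AI by giving the
randomly chosen better eye the group's base value and scaling the fellow
eye down by `(1+t)/(1−t)` with `t = AI/200` — this reproduces the drawn
AI exactly (AI is scale-invariant) while keeping every per-eye value
inside its physical bounds (perfusion ≤ 100%, circularity ≤ 1).
Demographics (age, sex, race, comorbidities, axial length, CMT, signal
strength) are drawn per group from the default cohort profile; HbA1c and
insulin status are generated only for diabetic groups and are missing —
explicitly, as empty fields — for non-diabetic controls. AI columns for
the seven metrics are mutually independent given the group, a
simplification: real fellow-eye metrics are correlated across metrics.

## Statistics

- **Path selection** is automated and auditable: per-group
  Kolmogorov–Smirnov tests against a fitted normal plus Levene's test;
  ANOVA only if all groups look normal and variances homogeneous at
  α = 0.05, otherwise Kruskal–Wallis. The chosen path and both check
  p-values are recorded in every result and in the analysis log.
- **Dunn's post hoc** is implemented directly (rank z-contrasts with tie
  correction `Σ(t³−t)/(12(N−1))`, Bonferroni over all pairs) and is used
  after both omnibus paths; no installed package provides it. Its oracle
  in the tests is a hand-ranked computation.
- **Categoricals**: Pearson chi-squared without continuity correction;
  when any expected count is below 5, Fisher's exact test (2×2) or a
  seeded Monte-Carlo conditional test on fixed margins (r×c, 20 000
  draws, flagged `fisher-mc` in the output).
- **Regression**: OLS with HC3 heteroscedasticity-robust standard
  errors — AI variance differs by an order of magnitude across severity
  groups, and classical standard errors undercover the injected HbA1c
  slope (measured 92% vs the nominal 95%; HC3 restores ~94–95%).
  Dummy coding: sex reference female, race reference the largest level,
  DR group as an ordered grade 0–3. A rank-deficient design raises a
  collinearity error naming the aliased columns. The ordered-grade
  adjustment absorbs the severity gradient only linearly, which
  attenuates the recovered HbA1c slope somewhat (≈0.6–0.7 recovered for
  0.8 injected); the CI coverage criterion is met because the bias is
  small against the slope's standard error.
- α = 0.05, two-tailed, throughout. Missing HbA1c rows are excluded
  listwise from HbA1c analyses.

## Problem sizes

Default experiment scales, chosen to give stable Monte-Carlo estimates at
desk scale: 500 null cohorts (4×30) for the type-I check; 100 cohorts at
the default group sizes (60/132/40/26) for severity-gradient power; 200
cohorts for regression CI coverage; 25 replicate cohorts for the
acceptance summary (group-mean standard errors a few percent); rendered
image checks at 96–245 px. Exact Fisher agreement is verified by full
enumeration over every 2×2 table with N ≤ 20 and non-degenerate margins.

## Known limitations

- The vascular generator's density units and vessel calibre are not
  device-matched; absolute density comparisons with clinical data are
  out of scope by design.
- Deep-layer (DRL) images are not rendered; deep AIs appear in the
  cohort model only.
- The FAZ contour estimator trades sharp-corner fidelity (+0.04 on a
  square's circularity) for smooth-boundary accuracy (±0.01 on discs).
- Ingesting a real per-patient supplementary table is supported through
  the documented CSV schema and a column-mapping hook, but no clinical
  dataset ships with the package; the ingestion path is exercised with a
  synthetic stand-in.
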