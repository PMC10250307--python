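# octa-asym

Interocular asymmetry analysis of the macular microvasculature from
en-face OCTA angiograms.

Diabetic retinopathy (DR) has traditionally been treated as a symmetric
disease of both eyes, and study protocols often enroll one randomly
chosen eye per patient. Optical coherence tomography angiography (OCTA)
makes that assumption testable: from a 3×3 mm en-face angiogram of each
eye one can quantify perfusion density, skeletonized vessel density and
the foveal avascular zone (FAZ), and ask how different the two eyes of
the same patient really are — and whether the difference grows with DR
severity. This package implements that analysis end to end for
researchers in ophthalmic imaging: a synthetic paired-eye angiogram and
cohort generator with known ground truth, the per-eye quantification
chain, the interocular asymmetry index, and the cohort statistics.

## The quantities

For each eye, from the binarized angiogram **B** (vessel = 1) and its
skeleton **S**:

- **Perfusion density** `PD = 100 · |B| / N` — percent of pixels occupied
  by vessels (SPD/DPD for the superficial/deep slab).
- **Vessel density** `VD = L(S) / A` — skeletonized centerline length per
  unit area, mm⁻¹, with 8-connected step lengths (1 px axial, √2 px
  diagonal) (SVD/DVD).
- **FAZ area / perimeter / circularity** — the central avascular
  component's area (mm²), sub-pixel contour length (mm), and the
  isoperimetric ratio `FAZC = 4π·FAZA / FAZP²` (1 for a disc).
- **Magnification correction** — Bennett-type scaling by
  `f = (AL − 1.82) / (AL_ref − 1.82)` for axial length AL
  (lengths ×f, areas ×f², vessel density ×1/f; dimensionless quantities
  unchanged).

Between fellow eyes (right = OD, left = OS), each metric yields an
**asymmetry index**

```
AI = |OD − OS| / (OD + OS) × 2 × 100      (%, range 0–200)
```

which is symmetric in the eyes and invariant to rescaling both eyes by a
common factor, so AIs are comparable across devices whose raw density
units differ. Cohort statistics follow clinical-study practice:
Kolmogorov–Smirnov and Levene checks select one-way ANOVA or
Kruskal–Wallis for the four-group comparison (no DM / DM without DR /
NPDR / PDR), followed by Dunn's rank post hoc with Bonferroni adjustment;
chi-squared (with an exact-Fisher fallback at expected counts < 5) for
categoricals; Pearson correlations; and covariate-adjusted OLS with
HC3 standard errors for the HbA1c–asymmetry relationship.

## Worked example

The numbered drivers under `analysis/` run the study pipeline on the
default synthetic cohort (258 patients, 60/132/40/26 across the four
severity groups, asymmetry increasing with severity):

```
$ python analysis/01_simulate_cohort.py 1
cohort: 258 patients (60/132/40/26)
mean AI of superficial perfusion density by group:
                mean    std
group
no DM           3.76   2.60
DM without DR   3.60   2.97
NPDR            5.12   3.73
PDR            19.96  15.56

$ python analysis/03_asymmetry_profiles.py 1
profiles for 258 patients; 0 mismatches vs stored AI columns

$ python analysis/04_cohort_statistics.py 1
four-group comparison of AI outcomes (method, omnibus p, PDR-vs-NPDR adjusted p):
  ai_spd   kruskal+dunn           p=3.77e-09  PDR-NPDR p=0.001
  ai_svd   kruskal+dunn           p=4.87e-09  PDR-NPDR p=0.000
  ...
significant HbA1c correlations:
    x       y     r     p   n
hba1c  ai_spd 0.235 0.001 198
hba1c  ai_svd 0.282 0.000 198
hba1c ai_fazp 0.232 0.001 198
hba1c ai_fazc 0.269 0.000 198
```

Reading this: the interocular asymmetry of superficial perfusion density
is small and similar in the three milder groups (mean AI ≈ 3.6–5.1%) but
several-fold larger in proliferative DR (≈ 20%); the omnibus and the
PDR-versus-NPDR contrasts reject decisively, and HbA1c correlates
positively with the asymmetry of the superficial densities and the FAZ
shape — the injected severity gradient and glycemia coupling are
recovered by the analysis chain. `02_quantify_angiograms.py` validates
the image chain itself against rendered ground truth (perfusion-density
error ≤ 0.01 percentage points; FAZ area within ~3%).

The same pipeline is scriptable over real data via the CLI:

```
octa-asym quantify --images scans/ --out run/      # TIFF + JSON sidecars
octa-asym asymmetry --out run/
octa-asym analyze --out run/ --cohort cohort.csv
```

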