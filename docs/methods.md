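# Methods

## Scope and data model

The package analyses 8-bit grayscale B-mode frames with physical pixel
spacing (defaults 0.017578 mm laterally, 0.0176 mm axially — the standard
resampling grid for 40 MHz small-animal liver imaging). Regions of
interest are 100-pixel circular disks; a pixel belongs to the disk iff its
center lies within `r = sqrt(area/π)` of the ROI center. This
center-in-disk rule is the simplest deterministic rasterization; the
realized pixel count deviates slightly from the nominal area (97 pixels for
area 100) and the rasterized disk carries the full 8-fold dihedral symmetry
of the grid. Coordinates are 0-based (row, col) with rows increasing with
depth; all physical quantities are millimetres. DICOM support is limited
to single-frame 8-bit MONOCHROME2 with a `PixelSpacing` tag; color or
multi-frame input is rejected rather than silently converted.

## Preprocessing chain

Feature extraction conditions each ROI in a fixed order:

1. **Smoothing.** 2D Gaussian on the ROI bounding-box patch with reflect
   padding, σ per axis = 0.018 mm / pixel spacing (≈ 1.02 px). The scale
   is specified in mm and could be read as σ or as FWHM; we use σ (the FWHM
   reading gives ≈ 0.43 px, a near-identity filter that would make the
   "speckle noise reduction" step vacuous). A σ below 0.25 px triggers a
   warning, not an error.
2. **Intensity correction.** Winsorization at μ ± 3σ (population SD over
   the in-disk pixels). Clipping rather than exclusion preserves ROI
   geometry for GLCM adjacency; exclusion is available behind a flag. A
   constant patch (σ = 0) passes through unchanged.
3. **Discretization.** Relative (min–max) binning into 256 levels:
   `level = floor((v − vmin)/(vmax − vmin)·256)` with the top edge closed.
   Relative binning makes the level grid — and hence every downstream
   feature — exactly invariant under positive affine transforms of
   intensity, which is the rationale for using these features across
   scanners and gain settings. A constant patch yields all-zero levels
   flagged degenerate; the GLCM is still defined. A fixed absolute bin
   width is not supported: on 8-bit data it cannot coexist with 256
   relative levels.

The order matters (clipping after discretization would change the level
grid whenever an outlier is present) and is asserted against in tests.

## GLCM and features

Co-occurrences are ordered pixel pairs at distance 1 along the four 2D
directions (0,1), (1,0), (1,1), (1,−1), pooled into a single matrix before
normalization and counted in both orientations (symmetric matrix; with
symmetric pooling μₓ = μᵧ by construction). Pairs with either pixel
outside the disk are excluded. The distance, direction set and pooling are
declared conventions (the common merged-matrix aggregation style), not
measurements; per-direction feature averaging is available by calling
`build_glcm` per direction. Sum entropy uses log base 2. With a single
occupied gray level the correlation denominator vanishes and correlation is
reported as NaN; subject-level averaging excludes and counts such values.
Per-animal features are arithmetic means over the lobe images of a session.

## Hepatorenal index

HRI = mean raw (pre-discretization) gray level of the liver ROI divided by
that of the renal-cortex ROI, both 100-pixel disks on the same frame. The
mean (not median) of the gray-level histogram is used. Both organs in one
view makes the ratio exactly invariant to a global gain factor. The same
100-pixel convention is reused for the renal ROI, which has no separately
standardized size.

## Statistics

* **Screening**: confusion counts of an imaging call against the
  histological reference (steatosis present ⇔ SSS total ≥ 1), with
  sensitivity, specificity, accuracy (correctly classified / N) and PPV;
  zero-denominator rates are NaN, not errors.
* **CUS positivity** is total ≥ 1 — the only rule consistent with the
  packaged joint counts, where the true negatives are exactly the CUS-0
  rows.
* **Data-derived cutoffs** are the maximum of the measure over a reference
  class (e.g. SSS = 0), with a strictly-greater-than classification rule,
  so the reference maximum itself classifies negative and specificity and
  PPV on the derivation set are 1 by construction. The indeterminate zone
  is (min over diseased, max over healthy), empty when the classes
  separate.
* **Correlation**: Spearman with average ranks for ties (rank-then-Pearson);
  two-sided p from the t approximation `t = r√((n−2)/(1−r²))` on n−2 df;
  95% CI from Fisher z with SE 1/√(n−3). The study names only the
  coefficient; the p and CI constructions are our documented choices.
  Correlations of imaging parameters are taken against the histological
  severity class (none/mild/moderate/severe = 0–3): on the packaged cohort
  this reproduces the published coefficient (r = 0.8614 vs 0.8598 printed),
  whereas correlating against the raw 0–7 SSS total gives 0.877.
* **Multiplicity**: Bonferroni, α/m with m = 6 (CUS, HRI, four GLCM
  features), threshold 0.00833.
* SSS totals 8–9 are arithmetically possible but outside the published
  class table; they map to "severe" with an out-of-table flag rather than
  being rejected.

## Speckle simulator

Fully developed speckle: per-pixel circular complex Gaussian scattering
with variance from a tissue map, blurred by an anisotropic Gaussian PSF
(FWHM 0.035 mm axial × 0.080 mm lateral; the probe datasheet gives
resolution ranges, not PSF shapes — Gaussian is a modelling choice), then
envelope → 20·log10(env/max) → clip to a 60 dB window → 8-bit. With a
near-delta PSF the envelope is Rayleigh and its point SNR (mean/SD) is
√(π/(4−π)) = 1.913, which the tests verify to 3% at n = 65,536.

The scene is a liver band, a renal-cortex band (variance fixed at 1), a
dark background (variance 0.01) and a bright specular band (variance
1.4 × 10⁴) standing in for the capsular/diaphragmatic interface that
dominates the display maximum on a fixed-gain scanner. Because the log
compression is referenced to the per-image maximum, this reflector sets
where parenchyma sits inside the 60 dB window; its strength was calibrated
once so the measured grade-0 HRI lands near the published no-steatosis
class mean, and then frozen.

Steatosis grade g ∈ {0,1,2,3} (mapped from the severity class:
none→0, mild→1, moderate→2, severe→3) controls the liver tissue through a
monotone table, calibrated once against the published per-class HRI
statistics and texture-trend directions and then frozen:

| g | ρ (liver/cortex variance) | τ (lognormal log-SD) | ℓ (mm, FWHM) | hypoechoic fraction | extra coherence (px) |
|---|---|---|---|---|---|
| 0 | 0.55 | 0.05 | 0.05 | 0.25 | 0.0 |
| 1 | 0.85 | 0.15 | 0.10 | 0.18 | 0.4 |
| 2 | 1.10 | 0.25 | 0.15 | 0.12 | 0.8 |
| 3 | 1.35 | 0.35 | 0.20 | 0.06 | 1.2 |

* ρ drives mean liver brightness and hence HRI.
* The lognormal heterogeneity field (log-SD τ, Gaussian correlation with
  FWHM ℓ, normalized to unit mean) models coarse parenchymal patchiness.
* The **hypoechoic fraction** models the fine dark vascular/sinusoidal
  structure of normal parenchyma as correlated blobs (scale 2 px, variance
  5% of liver) whose coverage *shrinks* with grade — fat infiltration
  obliterating small-vessel interfaces is the classic "vascular blurring"
  sign. The blob field is normalized so the liver mean variance stays
  exactly ρ.
* The **extra coherence length** models sub-resolution lipid droplets
  packing the tissue into a more coherent scatterer population: a small
  additional Gaussian smoothing of the complex field over the liver,
  power-renormalized so region brightness is unchanged; it coarsens the
  speckle grain with grade.

The last two parameters exist because ρ, τ and ℓ alone cannot move the
GLCM features: the μ±3σ clip and relative discretization make the features
nearly invariant to amplitude-only manipulations (by design), and a
lognormal field with ℓ ≤ 0.20 mm is almost constant across a 100-pixel ROI.
Structural texture changes — vanishing hypoechoic microstructure and a
growing speckle grain — are what real steatotic parenchyma shows, and they
produce the reported feature directions robustly: over 40 paired seeds,
liver-ROI GLCM contrast falls by ≈ 100–150 (of ≈ 1600) and sum entropy
rises by ≈ 0.03 bits from grade 0 to grade 3, while measured HRI rises
monotonically (≈ 0.72 / 0.92 / 1.06 / 1.16 against published class means
0.691 / 0.809 / 1.003 / 1.110).

What the simulator does **not** model: acoustic propagation, depth
attenuation, shadowing, probe geometry, electronic noise, TGC curves, and
anatomy beyond two rectangular organs. Passing tests therefore show that
the measurement chain behaves correctly on speckle statistics with the
right grade dependence — not that it was validated on real mouse images.

## Cohort generator

`simulate_cohort` rebuilds per-animal records from the packaged tables.
Exact mode emits one subject per joint-count cell (45 animals,
deterministic scores); resample mode draws group-conditional multinomials
over the observed cells with largest-remainder group allocation. Score
totals are split into components deterministically (SSS: fill macro, then
micro, then hypertrophy, each ≤ 3; CUS: parenchyma ≤ 3, then relative
echogenicity ≤ 2, then ascites), since components are not published per
animal. HRI is drawn from a truncated normal with the subject's (group,
SSS) cell mean/SD/range; single-animal cells yield the printed value; the
one cell whose printed mean lies outside its own printed range is stored
verbatim, flagged, and sampled untruncated. `run_pipeline` optionally
simulates one frame per animal at its class grade, measures HRI and
texture on it, and emits the screening, correlation, cross-tab and
min–max-normalized feature summaries as CSV plus a text summary.

## Problem sizes and numerical choices

Simulated frames are 256 × 256 (the matrix size is not standardized; this
holds both organs plus the reflector at the standard spacing). Generator
properties are tested at 20 seeds per grade with common seeds across grades
(paired comparisons); the acceptance script uses 40. Parameter recovery
(HRI → ρ) regresses mean HRI on log₁₀ρ — the display is linear in dB — and
inverts at held-out ρ values using the same seed set, a paired design that
isolates the map from shared speckle noise; recovery is within ±0.1 of ρ.
Tie-breaks and degenerate inputs: constant patches flag rather than raise;
empty GLCMs, empty reference classes, zero rank variance and zero renal
means raise typed errors. Known limitations: single-frame HRI has a
seed-to-seed SD of ≈ 0.13 (one 100-pixel cortex ROI dominates the noise),
matching the spread of the published per-class ranges; grade-adjacent
texture means are not strictly ordered at every intermediate grade — only
the grade-0 vs grade-3 contrast/entropy differences are claimed, at the
seed counts stated above.
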