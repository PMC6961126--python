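# Methods

This note documents the models, parameter choices and numerical
conventions behind `cardiopheno`, what the synthetic-data generators
do and do not emulate, and the design decisions taken where the
underlying analysis chains (originally embedded in commercial
instrument software) leave details open.

## Flow volumetry

The model treats a cell in suspension as a sphere whose forward-scatter
area (FSC-A) is linear in diameter over the calibrated range:
FSC-A = slope·d + intercept, fit by ordinary least squares on per-bead
FSC-A **medians** (robust to residual clumps) against known bead
diameters. R² = 1 − SS_res/SS_tot below 0.95 triggers a warning — the
standard symptom is an insufficiently mixed bead suspension.

Conventions chosen where the procedure is open:

* **Quantiles** use linear interpolation between order statistics
  ("type 7"), matching the default of mainstream plotting/spreadsheet
  tools, so the 7-value boxplot export (min, max, q25, q75, median ×3)
  reproduces what those tools would draw.
* **Non-physical events** (FSC-A ≤ intercept, i.e. d ≤ 0) are excluded
  and counted in `n_excluded`, not clamped; they are debris or
  below-range events, and clamping would bias the low tail.
* **Debris gating** has no published cutoffs; gates are user-supplied
  rectangular bounds. `suggest_debris_gate` offers the deepest valley
  of a kernel density estimate as an advisory starting point only.
* **Two-group comparison** uses the two-sided Wilcoxon rank-sum
  (Mann-Whitney) test: volume distributions are approximately
  lognormal, so a rank test is preferred over a t-test on the raw
  scale. Multi-group designs (ANOVA/Dunnett) are out of scope.

FSC arbitrary units are instrument-specific and treated as opaque;
only the bead calibration gives them physical meaning.

## Image segmentation

All operators work on 2-D channels with a physical pixel size
(default 0.65 µm/px, a typical 20× widefield configuration); areas and
distances are reported in µm.

**Sliding parabola.** The background estimate is the lower envelope of
the image under a paraboloid z(r) = −r²/(2·curvature) — a grey-scale
morphological opening with an additive structuring function, computed
exactly as two 1-D erosions followed by two 1-D dilations (the
paraboloid separates over axes on a square support; outside-image
pixels are treated as ±∞ so the opening is exact up to the border).
Larger curvature means a flatter paraboloid and more aggressive
removal; as curvature → ∞ the output tends to image − min. The opening
is idempotent exactly; repeated *subtraction* is stable up to the
residual's own envelope, which is small for structure sharper than the
paraboloid. Default curvature 10 (intensity units per px²).

**Nuclei detection.** Gaussian smoothing (σ = 1 px) → global threshold
at 0.40 × the robust per-image maximum (the 99.9th intensity
percentile; a 99.9th rather than the max makes the fractional
thresholds robust to hot pixels) → connected components → watershed
splitting of touching nuclei seeded at h-maxima of the Euclidean
distance transform → rejection of objects with area ≤ 30 µm² or shell
contrast ≤ 0.10 (contrast = (mean inside − mean of a 2-px surrounding
shell)/robust max). The published "split factor 27.5" is vendor-opaque;
here it maps to the h-maxima depth h_µm = split_factor/27.5 (default
1 µm), so larger values demand deeper valleys between seed maxima and
split less aggressively. Components whose distance-transform peak is
shallower than h keep a single seed and stay whole.

**Selection and clustering.** Nuclei are kept if area > 80 µm² and
roundness > 0.6, with roundness = 4πA/P² (P from the standard contour
perimeter estimator) clipped to [0, 1]; border-touching objects are
removed. Multinucleated cells are recovered by single-linkage
clustering of nuclei whose minimum edge-to-edge distance (between
boundary pixels on the µm grid) is ≤ 5 µm; clusters with total nucleus
area > 80 µm² become cells.

**Cytoplasm and perinuclear ring.** Cell territories come from a
seeded watershed on the smoothed, inverted cytoplasm counterstain,
restricted to pixels above 0.04 × robust max (unioned with the seeds,
so a blank channel degenerates to the seed regions); territories are
pairwise disjoint and contain their seeds. The perinuclear ring — the
compartment where retained proBNP accumulates — is the nucleus set
dilated by 0.75 × its equivalent radius (r_eq = √(area/π)) minus the
nucleus. The printed "−75%" resize is interpreted as outward expansion
(the ring must surround the nucleus to capture perinuclear signal);
the sign convention is a parameter.

## Phenotype logic

Percent outputs are exhaustive, mutually exclusive partitions and are
asserted to sum to 100 (mono+bi+multi; BNP neg+med+high;
organized+disarrayed; positive = medium + high).

**Thresholds from controls.** Marker positivity uses the 99th
percentile of a secondary-only/fibroblast control (≥ 20 control
cells). BNP cutoffs: neg_med = 95th percentile of the BOS-well
perinuclear intensities, med_high = 50th percentile of the ET1-well
intensities (≥ 50 cells each); both percentiles are configuration.
These defaults satisfy the two control expectations (>90% of BOS cells
negative, >90% of ET1 cells positive) and, on the default synthetic
intensity levels, give a med_high/neg_med ratio near the typical 4.
An inverted pair (med_high ≤ neg_med) flags overlapping controls with
a warning instead of raising. Boundary intensities are assigned to the
lower class (≤/>) so ties are never double-counted. Note that a
percentile taken exactly at a mixture's class boundary (e.g. the 95th
percentile of a well that is 95% negative) is an order statistic with
substantial sampling variance; control wells should be generously
sized.

**Texture features** (26 per cell, fixed order, over the
background-subtracted sarcomeric channel restricted to the cytoplasm):

* Haralick co-occurrence statistics (contrast, dissimilarity,
  homogeneity, ASM, energy, correlation) at distance 1 px, 4 symmetric
  directions averaged, 32 grey levels quantized over the region's
  1st–99th percentile range;
* a 6-angle Gabor bank with unit-L2 ("kernel") normalization. The
  published "scale 4 px, wavelength 2" is vendor-opaque; here the
  Gaussian envelope has σ = scale/2 px and the carrier period is
  wavelength·scale/2 px (4 px at defaults), so the passband covers the
  ~2.9 px striation period of a 1.9 µm sarcomere at 0.65 µm/px;
* Gaussian-derivative (spot/edge/ridge/valley/saddle/hole/bright/dark)
  response statistics at σ = 0.5 px, from the gradient, Laplacian and
  Hessian eigenvalues of the region-standardized intensity;
* radial profile statistics (4 bands of 4 px outward from the nucleus,
  plus slope and coefficient of variation) as an open substitute for
  proprietary radiality morphology features.

Intensities are z-scored within the region before filtering so the
features describe texture rather than staining brightness. Regions
under 50 px are flagged and excluded.

**Disarray classifier.** Features are standardized (train-set mean/sd)
and fit with a two-class linear discriminant (LDA, lsqr solver with
Ledoit-Wolf shrinkage — stable at 26 features with a few hundred
cells). Cells classify by the sign of the discriminant score.
*Goodness* is |µ₁ − µ₂|/√(σ₁² + σ₂²) of the **cross-validated**
discriminant scores (stratified 5-fold, deterministic split). Training
scores were rejected for this statistic: at this feature dimension
they are optimistically biased (indistinguishable classes yield ~0.36
rather than ~0), which would break the ">1 = well separated"
heuristic; on cross-validated scores the null concentrates near 0.07.
Training below 100 cells per class warns but proceeds.

## Mitochondrial energetics

Injections follow final = stock·v_inj/(v_inj + v_well) with dilution
factor (v_inj + v_well)/v_inj. OCR is normalized per 30,000 cells from
a per-well nuclei count (protein-based normalization is deliberately
unsupported: hypertrophy shifts protein/DNA). With window averages
A_w over [0–15], [20–35], [40–55], [60–75], [80–95] min:

    basal   = A_basal − A_medium        maximal = A_fccp − A_rotenone
    atp     = A_basal − A_oligomycin    spare   = A_fccp − basal
    non_mito = A_rotenone               leak    = A_oligomycin − A_rotenone

The formula set uses the post-medium window [80–95] as basal's
non-mitochondrial reference but the post-rotenone window [60–75]
everywhere else; both windows estimate non-mitochondrial O₂
consumption and the asymmetry is reproduced deliberately
(`single_non_mito_window=True` unifies them, with a log note).
Windows are configured in minutes, not hard-coded indices, to tolerate
instrument timing drift. Two useful consequences hold on every trace
and are asserted in tests: atp + leak = A_basal − A_rotenone, and
spare − maximal = A_rotenone − A_basal + A_medium. On a constant trace
all difference parameters are 0 except spare = non_mito = c (spare
subtracts basal, which is 0, from A_fccp = c).

ΔΔCT: ΔCT = CT_mito − CT_nuclear per sample; ΔΔCT subtracts the
arithmetic mean control ΔCT (equivalently, the geometric mean on the
fold scale, so multi-sample control groups average to ~1 rather than
exactly 1). The default fold convention is 2^ΔΔCT; the `canonical`
switch gives 2^(−ΔΔCT), under which a sample with more mtDNA shows
fold > 1 — the generator and recovery tests use `canonical` because it
matches content directly. MT-ND1 and MT-ND2 are reported separately,
never averaged.

## Synthetic data: what it does and does not emulate

The generators define the study conditions for all recovery tests.

* **Flow**: bead FSC = (100·d + 50)·(1 + N(0, cv)), default cv 2%
  (typical instrument CV); cell volumes lognormal (default median
  4000 µm³, geometric SD 1.5 — a realistic hPSC-CM spread); SSC scales
  with d²; optional low-scatter debris.
* **Scenes**: cells on a jittered 50 µm grid (guaranteed
  non-overlapping); nuclei as ellipses of radius ~6 µm (areas safely
  above the 80 µm² filter); sibling nuclei placed 1–2.5 µm apart
  (well inside the 5 µm clustering distance, while inter-cell nucleus
  gaps stay > 8 µm); organized sarcomeres as a coherent zero-mean
  grating at the physiological 1.9 µm period, disarray as isotropic
  band-pass noise in the same spatial band plus bright puncta
  (orientation decorrelation is exactly the property the Gabor/Haralick
  set is sensitive to); BNP as class-level lognormal ring intensities
  (baseline/medium/high mean levels 30/240/900 over an α-actinin base,
  chosen so the derived med_high/neg_med ratio lands near the typical
  4); Poisson shot noise plus Gaussian read noise (σ = 2).
  Not emulated: optics beyond Gaussian blur (no PSF/defocus), uneven
  illumination, cell-shape irregularity, overlapping/confluent growth,
  z-structure. Passing recovery tests therefore demonstrates the
  correctness of the analysis logic, not robustness to every
  real-microscopy artifact.
* **OCR**: three measurements per 15-min window at the five protocol
  phases; multiplicative Gaussian noise; negative draws floored at 0
  with a logged count.
* **qPCR**: case mito CT shifted by −log₂(fold); per-well Gaussian CT
  noise; nuclear CT varies by 0.3 cycles across samples.

Determinism: every generator consumes a single `numpy` Generator
seeded explicitly; identical seeds give bitwise-identical outputs.

## Problem sizes and tolerances

Recovery tests use 100–300-cell scenes and the acceptance script
500-cell wells with 200 + 200 classifier training cells — large enough
that counting statistics (±~2–4 points at 95% margins) sit inside the
stated ±5-point tolerances, and comfortably desk-scale. Flow recovery
uses 100,000 events (median within 2%); ΔΔCT recovery averages
10 + 10-sample plates over repeated seeds at 0.1-cycle CT noise.
Numerical tolerances: sphere-formula and round-trip identities at
1e-9 relative; rasterization-dependent geometry (ring area, roundness)
at 5%.

## Known limitations

* Rectangular gating only; no fluorescence compensation, log-scale
  transforms or FCS parsing (CSV event tables).
* 2-D segmentation only; images are assumed flatfield-corrected.
* The proprietary texture/morphology feature definitions (SER, STAR)
  are approximated by documented open formulations; absolute feature
  values are not comparable to vendor output, though the downstream
  classification logic is.
* Two-group statistics only.
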