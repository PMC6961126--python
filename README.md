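# cardiopheno

Open, testable phenotyping pipelines for human pluripotent stem
cell-derived cardiomyocytes (hPSC-CMs), targeting the cellular
hallmarks of hypertrophic cardiomyopathy (HCM): cell enlargement,
multinucleation, hypertrophic-marker (proBNP) induction, sarcomeric
disarray, and altered mitochondrial energetics.

These read-outs are usually computed inside closed commercial software
(cytometer analysis suites, high-content imagers, extracellular-flux
analysers). `cardiopheno` re-implements the analysis logic as explicit,
inspectable Python operations, and ships synthetic-data generators with
known ground truth so every pipeline can be validated end to end
without instrument data.

## What it computes

**Flow volumetry** (`cardiopheno.flow`). Calibration beads of known
diameter define a linear map FSC-A = *slope*·*d* + *intercept* (fit by
OLS on per-bead FSC-A medians; R² ≥ 0.95 is the quality gate). Each
gated cell event is then inverted to a diameter
*d* = (FSC-A − intercept)/slope and a spherical volume
*V* = (π/6)·*d*³. Distributions are summarized by the 7-value boxplot
export (min, max, q25, q75, median ×3) and compared with a two-sided
rank-sum test.

**Image segmentation** (`cardiopheno.segmentation`). Sliding-parabola
background subtraction (grey-scale opening with a paraboloid
structuring function); DAPI nuclei detection (threshold 0.40 of the
robust max, area > 30 µm², watershed splitting, contrast > 0.10);
nucleus selection (area > 80 µm², roundness 4πA/P² > 0.6, border
removal); cluster-by-distance grouping of nuclei into cells
(edge-to-edge ≤ 5 µm, single linkage) for multinucleation; seeded
watershed cytoplasm delineation on the CellMask/cTnT channel
(threshold 0.04); perinuclear ring construction (nucleus dilated by
75% of its equivalent radius, minus the nucleus).

**Phenotype logic** (`cardiopheno.phenotypes`). Percent mono-/bi-/
multinucleated cells; cardiomyocyte purity against a secondary-only or
fibroblast control threshold; BNP negative/medium/high classes with
thresholds derived from bosentan (BOS, negative) and endothelin-1
(ET1, positive) control wells; and sarcomeric disarray via a
26-dimensional texture feature set (Haralick co-occurrence at 1 px,
a 6-angle Gabor bank, Gaussian-derivative spot/edge/ridge responses at
0.5 px, radial profile statistics at 4 px) feeding a standardized
linear discriminant whose cross-validated "goodness" (>1 = separated)
diagnoses training quality.

**Mitochondrial energetics** (`cardiopheno.mito`). Port-injection
dilution arithmetic; OCR normalization per 30,000 cells; the six
mitostress parameters from window averages (basal, maximal, ATP-linked,
spare capacity, non-mitochondrial, proton leak); and relative mtDNA
content by the comparative-CT method,
ΔCT = CT(MT-ND1/2) − CT(ACTB), ΔΔCT vs the healthy-control mean,
fold = 2^ΔΔCT (a `canonical` 2^(−ΔΔCT) switch is provided).

**Synthetic data** (`cardiopheno.synthetic`). Generators for all four
input classes — bead/cell scatter events, multi-channel
immunofluorescence scenes (elliptical nuclei, striated vs
orientation-decorrelated sarcomere textures, class-level perinuclear
BNP rings, Poisson + read noise), OCR plateau traces, and qPCR CT
plates — each returning a ground-truth record and bitwise-reproducible
under a fixed seed.

## Worked example

```python
from cardiopheno import (simulate_flow_events, fit_bead_calibration,
                         events_to_volumes, summarize_volumes,
                         compare_volume_distributions)

healthy = simulate_flow_events(
    noise_cv=0.02, seed=1,
    cell_pops=[{"median_volume_um3": 4000.0, "geometric_sd": 1.5,
                "n": 100_000}])
hcm = simulate_flow_events(
    noise_cv=0.02, seed=2,
    cell_pops=[{"median_volume_um3": 5200.0, "geometric_sd": 1.5,
                "n": 100_000}])

curve = fit_bead_calibration(healthy.bead_panel)
va = events_to_volumes(healthy.cell_events, curve)
vb = events_to_volumes(hcm.cell_events, curve)
box = summarize_volumes(va)
res = compare_volume_distributions(va, vb)
```

which prints, via the obvious f-strings:

```
calibration: FSC-A = 100.00 x d + 49.93  (R^2 = 1.0000)
healthy median volume: 3992 um^3  (IQR 3030-5259)
HCM-like vs healthy: +30.6% median volume, p = 0.00e+00
```

The calibration recovers the generator's slope/intercept (100, 50);
the healthy median matches the simulated 4000 µm³ within sampling
error; and the simulated 30% hypertrophic volume shift is recovered as
+30.6% with an overwhelming rank-sum significance.

The same pipelines are scriptable from the shell, e.g.:

```sh
phenotype simulate scene --n-cells 100 --seed 1 --out fixtures/
phenotype segment --image fixtures/scene.tif --pixel-size 0.65 --out seg/
phenotype mito stress --trace ocr.csv --counts counts.csv --out res/
```

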