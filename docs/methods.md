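# Methods

## Scope and rationale

phenoscope re-implements, as reusable and tested code, the image
quantification used in microscopy-based phenomic screening of yeast
GFP-fusion collections: paired per-cell intensity fold-change
screening, 3D mitochondrial morphometry with the size-normalized
mitochondrial fraction, nucleus-centered line-profile localization
scoring with a six-way change classifier, and the accompanying
growth/expression statistics. Because raw screen images of this kind
are rarely public, the package ships a synthetic-micrograph generator
with voxel-exact ground truth; every pipeline stage is validated
against injected truth rather than against irreproducible manual
scoring.

## Synthetic acquisition model

**Geometry.** Volumes are `(z, y, x)` arrays; the voxel `(k, j, i)`
center sits at `((k+0.5)·Δz, (j+0.5)·p, (i+0.5)·p)` μm. Defaults:
lateral calibration `p = 0.1038` μm/px (from the instrument's printed
scale of 60 px = 6.23 μm), axial step `Δz = 0.3` μm (the instrument's
true step is not recoverable; declared, configurable), 30 slices per
stack. Cells are spheres; the nucleus is a concentric sphere at 0.35 of
the cell diameter (yeast nuclei occupy roughly a third of the cell
diameter; the exact value is configurable). Cells must fit laterally;
axial clipping is allowed, as a confocal stack samples a slab.

**Fluorescence classes.** GFP is painted per cell as a multiple of its
`intensity_scale` s: cytoplasmic (1.0·s uniform), nuclear (0.6·s
cytoplasm, 2.4·s nucleus — a 4× contrast so nuclear enrichment survives
PSF mixing), punctate (0.4·s base plus narrow Gaussian foci, σ =
0.12 μm, amplitude 6·s), mitochondrial (0.15·s matrix plus 3·s on a
tubule network), periphery (0.3·s interior, 2.5·s in a 0.30 μm cortical
shell). Mitochondrial tubules are persistent random-walk polylines
(step 0.35 μm, z-motion damped 4×, reflected at 0.85 of the cell
radius, start points stratified on a golden-angle spiral so separate
tubules stay distinct) dilated to a spherocylinder radius of 0.28 μm.
When a target network volume is requested, segments are added until the
rendered voxel volume reaches it (the last segment is dropped if that
lands closer), making injected volumes exact to about half a segment
despite tubule overlap. The helper `volume_matched_tubule_params`
solves `n(π r² L + 4/3 π r³) = V` so fragmented (many short) and fused
(few long) phenotypes can be built at equal nominal volume.

**Optics and noise.** The PSF is an anisotropic Gaussian (defaults
σ_xy = 0.15 μm, σ_z = 0.45 μm — lateral/axial widths typical of a
spinning-disk confocal at high NA). Fluorescence channels then receive
Poisson shot noise (default 100 photons per intensity unit) and
Gaussian read noise (default σ = 1.5 units). The brightfield channel —
a dark disk with a bright rim on a mid-grey background, a deliberately
schematic stand-in for transmitted-light contrast — receives read noise
only, since shot noise is negligible at transillumination flux. No
photobleaching, spectral bleed-through or camera-gain modeling.

**Determinism.** All randomness flows from one integer seed through
`SeedSequence([seed, *keys])` with documented integer keys per channel,
cell, gene, genotype and field; identical inputs give bit-identical
output.

**Ground truth.** Label volumes for cells, nuclei and mitochondria,
plus a per-cell table of class, geometry, rendered volumes (voxel count
× voxel volume, exactly) and the noise-free post-PSF mean GFP in 3D and
under max/mean projection — so estimator bias can be separated from
noise realization.

**Dense-field layout.** Screen-like fields (35+ cells) cannot be placed
by rejection sampling, so cells sit on a jittered grid with a
configurable margin; diameters are normal draws truncated at ±2.5 sd so
neighbors cannot collide. Per-cell brightness is lognormal with CV 0.20
(typical cell-to-cell expression noise); that CV sets the ~3% sampling
error of a 90-cell fold-change estimate and hence the screen's
operating characteristics.

## Segmentation and cell volume

Mid-stack brightfield slice → 3×3 median filter → Sobel edge magnitude
→ Otsu threshold → closing, hole filling → erosion by 2 px (the edge
band extends to the outer side of the blurred rim; shrinking by its
half-width re-centers the boundary) → distance-transform watershed
seeded at regional maxima (min separation 10 px). Regions outside
100–5000 px² are dropped; border-touching cells are flagged and, by
default, excluded from statistics. Diameters are the major/minor axes
of the best-fit ellipse (second central moments, the regionprops
normalization); cell volume is the sphere at the mean diameter. The
Sobel/Otsu front end makes segmentation exactly invariant to global
intensity rescaling. On the validation fields (40 cells, 3 μm), recall
is ≥ 95% with mean IoU ≈ 0.96 against ground truth.

Nuclei are detected on the max-projected DAPI channel by Otsu; within
each cell the largest blob wins, ties broken by lower blob label;
cells without a blob are flagged rather than guessed.

## Intensity screen

Per-cell mean GFP is measured on a z-projection (maximum-intensity by
default, selectable) over the segmented region; the screen statistic is
the mutant/WT ratio of field-averaged per-cell means. With two fields
per genotype, field k is paired with field k and the two ratios
averaged. Genes with fewer than 35 cells in either genotype (the
acquisition floor per field) are excluded as low-coverage. Ranking is
by fold change descending with lexicographic tie-break; primary hits
are strict `fc > 1.3` or `fc < 0.7`; confirmation requires an
independent second round to reproduce the call in the same direction.
Projection noise and the read-noise floor compress measured folds
toward 1 by ~2–4%, far inside the hit margins at the exemplar effect
sizes (1.65, 0.51, 3.77).

## Mitochondrial morphometry

Per cell, the GFP subvolume is sharpened by 10 Richardson–Lucy
iterations against the declared Gaussian PSF, then thresholded at the
half-maximum between the background mean (voxels at or below Otsu's
value) and the tubule plateau, estimated as the 90th percentile of the
above-Otsu voxels. Two choices matter here. First, without
deconvolution the axial PSF halo of sub-resolution tubules inflates
thresholded volumes ~2.4×; after sharpening, volumes are within ~3% of
truth (Dice ≈ 0.84). Second, the plateau estimate must not drift with
network density: a whole-volume percentile reads deeper into the bright
core for dense networks than sparse ones, biasing strain comparisons by
~20%, while the foreground-quantile reference measures sparse and dense
networks identically. A structureless guard (upper tail within 5 robust
sd of the median) returns an empty mask for flat or noise-only input,
and components under 5 voxels are removed as speckle.

Volume is voxel count × voxel volume; surface area counts exposed voxel
faces with anisotropy respected (a deterministic staircase measure that
overestimates smooth surfaces by up to ~1.5×, which cancels in
within-study comparisons). Elongation features come from the 3D
topological skeleton: total length sums physical distances over
26-adjacent skeleton voxel pairs (each edge once), branch points are
skeleton voxels with ≥ 3 neighbors, components use 26-connectivity.
Skeletonization recedes from tubule ends by about one radius, so a
straight L = 5, r = 0.3 μm cylinder reads ~4.4 μm — ratios between
conditions, which is what the elongation analysis uses, are unaffected.

The mitochondrial fraction divides each cell's mitochondrial volume by
the strain's **mean** sphere-approximated cell volume (per-cell mode
available but off by default), with a 50-cell floor per analysis
(flagged, not fatal). The validation contrast injects a 3.0× network
volume and 1.76× cell volume and recovers the 3.0/1.76 ≈ 1.70 fraction
ratio within 10% (mean over seeds); residual error is dominated by
cell-size sampling (σ ≈ 3.5% at 54 cells/strain) plus a ~2–3%
systematic from boundary placement on different-sized cells.

## Localization profiling and categorization

Line profiles sample 60 points one pixel apart (6.23 μm total) by
bilinear interpolation along a line through the nucleus centroid,
horizontal by default; the center sample (index 30) lies on the
centroid, and samples leaving the frame are NaN. Replicate means are
averaged pointwise with equal replicate weight regardless of cell
counts.

Per-cell features on the max projection: nuclear mean (disk matched to
the detected DAPI blob area), peripheral mean (3 px boundary shell),
cytoplasmic mean (the remainder), their nuclear/cytoplasmic (nc) and
peripheral/cytoplasmic ratios, punctum count (smoothed local maxima
above 2× the cell median, min 3 px apart), intensity CV, and the 2D
skeleton length of the above-Otsu signal. A cell is "nuclear" when
nc-ratio > 1.5 (the notion of prominent enrichment is inherently a
convention; the cut is configurable and the 4× rendered contrast makes
the call insensitive to it); percent-nuclear is the flagged share of
scoreable cells, requiring 50 cells.

Change categorization replaces three-researcher visual calls with an
ordered rule list over population medians: (1) punctate if punctum
count rises ≥ 3 and CV rises ≥ 50%; (2) nucleus↔cytoplasm if the
median nc-ratio crosses 1.5; (3) periphery→cytoplasm if the
peripheral ratio falls from ≥ 1.2 to below it; (4) mitochondrial
elongation if median skeleton length rises ≥ 50% from a baseline of at
least 1 μm (sub-micrometre skeletons are thresholding noise, not
tubules — without this floor, null pairs of diffuse cells occasionally
trip the ratio test); (5) otherwise abundance change if the fold leaves
the (0.7, 1.3) band; else no change. Structural rules precede the
abundance rule so a punctate shift with increased abundance is called
punctate. All thresholds live in a `CategoryRules` dataclass. On the
seven-condition benchmark (six categories plus a null pair, ~40 cells
per population) the classifier recovers ≥ 90% of categories across
seeds.

## Assay statistics

Doubling time: least squares of ln OD on time over the closed
[3, 7.5] h window, `T_d = ln 2 / slope`; with exactly two points this
is algebraically `Δt·log 2 / log(OD₂/OD₁)` (the log base cancels;
natural log internally). A non-positive slope raises a no-growth
signal. The generator's logistic trajectory has early-exponential
doubling equal to its parameter; round-trip validation uses a carrying
capacity far above the window ODs, since the estimator is defined for
the exponential regime.

ΔΔCt: per replicate, ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts
the baseline strain's mean ΔCt; relative expression is `2^−ΔΔCt` with
amplification efficiency fixed at 2 (standard-curve correction out of
scope). Technical/biological pairing is per-replicate ΔCt first, then
strain aggregation; the baseline's geometric mean is exactly 1, and the
result is invariant to adding a constant to every Ct.

Normalizations are plain ratios (band ÷ total protein; readout ÷ WT
mean) with zero denominators rejected by name.

Population comparisons: two groups → Welch's unequal-variance t-test;
more → one-way ANOVA with Tukey's HSD at α = 0.05 (scipy's
studentized-range implementation; cross-checked against statsmodels in
the tests). Degenerate groups (n < 2, zero variance) are rejected with
the group named. Under a three-equal-mean null the observed family-wise
error is at the nominal 5% (≤ 7% in 1000 simulations).

## Validation studies and problem sizes

`phenoscope.studies` fixes the validation conditions: segmentation
fidelity on ten 40-cell fields; the screen at 360 genes × 2 genotypes ×
2 fields × 45 cells on a reduced acquisition (3 slices, 248² px, same
calibration and noise) — sized so a three-seed, two-round validation
runs in minutes while preserving the per-cell statistics the fold
change depends on; the mitochondrial contrast at 3 replicates × 18
cells per strain (54 cells/group, above the 50-cell floor) on 18-slice
stacks; localization at 60-cell fields. These sizes are the package's
declared operating points, not limits of the method.

## Known limitations

* The brightfield model is schematic (disk + rim); real transmitted
  light optics (defocus rings, mother-daughter necks) will challenge
  the edge-based segmentation and are out of scope, as are
  learning-based segmenters and time-lapse tracking.
* Surface areas are staircase measures; absolute values should not be
  compared with mesh-based tools.
* The synthetic generator draws cells as spheres on a grid with
  independent lognormal brightness; it does not emulate buds, vacuole
  shadows, focus drift, dead cells or spatial intensity gradients, so
  passing validation bounds measurement error under the declared
  optics/noise model only — it does not certify performance on real
  micrographs.
* Equivalence with any particular plugin's internal thresholding is
  not claimed; mitochondrial volumes are internally consistent and
  truth-calibrated on synthetic data instead.
* ΔΔCt assumes perfect doubling per cycle; efficiency estimation from
  dilution series is out of scope.
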