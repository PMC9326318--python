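# Methods

## Model and pipeline

A subject contributes three coregistered scalar volumes — plasma volume Vp
(mL/100 mL, DCE-MRI), ¹⁸F-FAZA uptake (arbitrary/SUV-like units, PET), and
mean diffusivity MD (mm²/s, DTI) — plus one or two binary tumor masks
(contrast-enhancing core "CE"; the wider FLAIR-hyperintense volume "FLAIR").
The pipeline is deliberately simple and fully deterministic:

1. **Resampling.** All volumes are brought onto one axis-aligned 1 mm
   isotropic RAS+ grid (trilinear for maps, nearest-neighbour for masks).
   Registration is out of scope: inputs are assumed coregistered, and only
   grid resampling is performed. Target voxels outside the source volume
   become NaN and are treated as outside the mask everywhere downstream.
2. **Voxel inclusion.** Per map, in-mask voxels outside mean ± k·SD
   (default k = 3) of the in-mask distribution are excluded — a guard
   against segmentation spill-over and reconstruction artifacts. Mean and SD
   are population statistics over finite in-mask values.
3. **Otsu binarization.** A global threshold per map per subject maximizes
   the between-class variance σ_b² = ω₀ω₁(μ₀−μ₁)² over a 256-bin histogram
   of the included values. The threshold is the upper edge of the selected
   bin; ties break toward the smallest threshold; the low class is
   {v ≤ T}. Because the threshold is re-estimated per subject, the habitat
   map is invariant to any positive rescaling of a map — no inter-scanner
   intensity harmonization is attempted (the cohort the fixtures describe
   mixes 1.5 T and 3 T scanners), and none is needed for this statistic.
4. **Intersection.** The (Vp, FAZA, MD) high/low triple indexes habitats
   1–8 in the fixed order HHH=1 … LLL=8. Voxels excluded on any map get
   label 0 and are omitted from fraction denominators (configurable:
   `excluded_policy="nearest-cluster"` instead assigns them against the
   threshold, which never sees them during estimation).

A constant map raises an error by default (`allow_degenerate=True` labels
everything low instead): a flat clinical map indicates an upstream fault, not
a tumor with one tissue class. A multifocal mask is one voxel set with one
global threshold. An ROI must contain ≥ 2 voxels with nonzero intensity range
to be thresholdable.

## Statistics

Habitat **fractions** are 100·|label = h| / |labels 1..8| per subject — pure
count ratios, invariant to voxel volume. The denominator is the assigned
voxels, not the whole ROI; "% of total tumor volume" is ambiguous once voxels
are excluded, and excluding label 0 from the denominator keeps the eight
fractions summing to exactly 100. **Medians** are per habitat per map, with
MD conventionally scaled ×10³ for tables; an empty habitat is missing (NaN),
never 0. Cohort tables take unweighted across-subject means.

Group comparisons are nonparametric: Mann-Whitney U (exact p by full
enumeration when max(n) ≤ 20 and the pooled sample has no ties — the
enumeration null assumes continuity — otherwise tie-corrected normal
approximation), Kruskal-Wallis with tie correction and χ²(k−1) p, and Dunn's
pairwise z on pooled ranks with Bonferroni factor k(k−1)/2 capped at 1.
Survival is summarized descriptively only (mean, SD, median, range of OS
weeks); no Kaplan-Meier or regression is fitted.

One reporting note: the fixtures' habitat-7-by-IDH-1 comparison (n = 14 wild
type vs 3 mutated) gives U = 35 with exact two-sided p = 0.0912; the
one-sided exact p is 0.0456. Published analyses of such tables sometimes
print the one-sided value as "P = 0.05"; this package reports the two-sided
p as primary and exposes both.

## Biopsy VOIs

A stereotactic target is sampled with a 5-mm-diameter sphere (the magnitude
of reported stereotactic accuracy error); membership is by voxel-center
Euclidean distance, without partial-volume weighting — on a 1 mm grid a 5 mm
sphere holds 63–81 voxels depending on where the center falls relative to
the lattice. Habitats inside the VOI are ordered by descending voxel count,
ties by ascending label, so output is total-ordered and deterministic.
Histology grades (cellularity 1–5; necrosis classes 0–5 covering 0%, ≤10%,
11–25%, 26–50%, 51–75%, 76–100%; hyperplastic vessel counts) describe the
central 5 mm segment of the physical specimen and are joined descriptively;
no inferential test is attached to the correlation table.

## Synthetic phantoms

The generator emulates the *data model* of the clinical inputs, not their
biophysics. A tumor is five concentric ellipsoidal shells (habitats, inner →
outer: 5, 2, 1, 6, 8) plus an outer edema halo of habitat 7; the CE mask
covers the shells with contrast-enhancing habitats {1, 2, 5, 6}, the FLAIR
mask everything, so CE ⊂ FLAIR. Each voxel's truth habitat fixes a high/low
level per map and values are drawn Normal(μ_level, σ) with
σ = (μ_H − μ_L)/separation; defaults Vp 1.0/4.9 mL/100 mL, FAZA 0.3/1.4,
MD 0.98/1.32 ×10⁻³ mm²/s, separation 4. MD is clipped at 0. A
`speckle_fraction` (default 5%) of voxels in the outer shells is re-labeled
to habitats 3/4 as scattered single-voxel clusters, mimicking how those
habitats appear only as fragments in real tumors.

**Default geometry.** Default radii (19.0, 23.8, 27.2, 29.9, 32.2, halo
36 mm on a 96³ grid) give the five shells near-equal volumes with a double
share for the halo. This is a deliberate harness choice rather than an
imitation of clinical volume proportions: with Gaussian class noise at
separation s the per-map misclassification rate is Φ(−s/2) (≈ 2.3% at
s = 4), and a habitat occupying ~1% of the tumor adjacent in code space to
one occupying ~50% would receive misclassification influx exceeding its own
size several times over, capping its Dice near 0.5 no matter how correct the
implementation. Balanced zones make per-habitat Dice a stable recovery
statistic: every concentric habitat recovers with Dice ≥ 0.92 at 4σ and
exactly 1.0 with zero noise. Recovery checks under noise therefore run with
`speckle_fraction=0` — voxel-scatter habitats cannot meaningfully be scored
by overlap under noise — while the zero-noise check keeps the speckles.

What passing phantom tests does **not** show about real data: the phantom
has piecewise-constant tissue classes with i.i.d. Gaussian noise, no spatial
noise correlation, no partial-volume mixing at zone boundaries, no
registration error between maps, and exactly two intensity levels per map.
Real maps violate all of these; the phantom validates the pipeline's
correctness, not its clinical adequacy.

The cohort generator jitters shell *thicknesses* (±10%) rather than radii,
so radii stay strictly increasing, and jitters level means ±10% per subject;
everything derives from a single seed.

## Numerical choices

- Otsu histogram: 256 bins over [min, max] of included values; class means
  use bin centers. On near-flat σ_b² plateaus the histogram maximizer may sit
  a few bins from the exhaustive midpoint maximizer while achieving variance
  within 0.1% of the optimum; the test suite accepts either.
- Boundary convention v > T → high, v ≤ T → low, fixed and documented.
- Grids are compared with 1e-6 mm tolerance; identical grids short-circuit
  resampling so the identity resample is bit-exact.
- Trilinear interpolation is a convex combination, so resampled values never
  overshoot the source range.
- Printed-table comparisons in tests use |Δ| ≤ 0.1 (0.05 computational slack
  + 0.05 last-printed-digit rounding); e.g. the habitat-2 cohort average
  recomputes to 12.15 against a printed 12.1.

## Fixtures

The packaged CSVs transcribe a published 17-patient high-grade-glioma
cohort: clinical/molecular records, per-patient habitat volume fractions,
per-habitat map medians, and the stereotactic biopsy histology table
(31 samples from 10 patients). Files are sha256-checksummed and verified at
load. Categorical symbols were normalized at transcription (IDH-1 +/− →
mutated/wild-type; MGMT +/−/N/A → methylated/unmethylated/unknown). Two
printed values are knowingly not exactly reproducible from the printed
per-patient numbers and are documented rather than corrected: the cohort
mean CE/FLAIR volume ratio (printed 0.30), and a grouped habitat-7 mean
printed as 33.3% in prose but 33.0% in the corresponding table (the
per-patient values give 33.02%).

## Known limitations

- No registration, bias-field, or distortion correction; garbage-in applies.
- Only axis-aligned RAS+ grids are supported; oblique acquisitions must be
  reoriented upstream.
- The two-class-per-map assumption is inherent to Otsu; maps with more than
  two tissue populations are force-split (k-means-style multi-class
  clustering is explicitly out of scope).
- Exact Mann-Whitney enumeration falls back to the asymptotic form whenever
  ties are present, even at small n.
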