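# gliohab

Spatial habitat mapping of high-grade gliomas from coregistered
multi-parametric PET/MRI volumes.

High-grade gliomas are spatially heterogeneous: contrast-enhancing vital
tumor, necrosis, infiltration, and vasogenic edema coexist within one lesion
and respond differently to therapy. `gliohab` implements a voxel-wise
"habitat imaging" analysis that partitions a tumor into eight physiological
subregions by combining three quantitative maps:

- **Vp** — plasma volume from DCE-MRI (perfusion / neoangiogenesis),
- **FAZA** — ¹⁸F-fluoroazomycinarabinoside PET uptake (hypoxia),
- **MD** — mean diffusivity from DTI (inversely related to cellularity).

## Method

Inside a tumor mask (FLAIR-hyperintense volume by default), each map `D` is
binarized into low/high clusters `D → [D_L, D_H]`, `D_L ∩ D_H = ∅`, at a
global Otsu threshold `T` — the histogram cut maximizing the between-class
variance

```
σ_b²(t) = ω₀(t) ω₁(t) (μ₀(t) − μ₁(t))²
```

after excluding voxels outside mean ± 3 SD of the in-mask distribution. The
three binary volumes are intersected into 8 habitats, e.g.
`Habitat(HHH) = D1_H ∩ D2_H ∩ D3_H`:

| habitat | Vp | FAZA | MD | interpretation |
|---|---|---|---|---|
| 1 | H | H | H | perfused, hypoxic vital tumor (peripheral core) |
| 2 | H | H | L | most aggressive vital core (high cellularity) |
| 3 | H | L | H | fragmented, near vessels/cortex |
| 4 | H | L | L | fragmented, near vessels/cortex |
| 5 | L | H | H | necrosis with residual vital tissue |
| 6 | L | H | L | pre-necrotic / progressing seeds |
| 7 | L | L | H | vasogenic edema |
| 8 | L | L | L | infiltrative edema / low-MD tissue |

Downstream analyses: per-habitat volume fractions and map medians, cohort
tables with grouped summaries (IDH-1 status, WHO grade), nonparametric tests
(Mann-Whitney U with exact small-sample p, Kruskal-Wallis, Dunn-Bonferroni),
and 5-mm spherical VOI sampling at stereotactic biopsy coordinates with
prevalence-ordered habitat profiles for histology correlation.

Because patient imaging of this kind is rarely shareable, the package ships a
synthetic phantom generator (`gliohab.synthetic_data`) producing concentric
tumor zones with known ground-truth habitats, plus checksum-verified fixtures
of a published 17-patient cohort's clinical and habitat-fraction tables.

## Worked example

```
python examples/01_phantom_to_habitats.py
```

```
Otsu thresholds (map units):
    Vp: T = 2.915  (24 of 195360 voxels outlier-excluded)
  FAZA: T = 0.8586  (1 of 195360 voxels outlier-excluded)
    MD: T = 0.001149  (0 of 195360 voxels outlier-excluded)

Habitat volume fractions (% of assigned tumor volume):
  habitat 1:  14.0
  habitat 2:  13.9
  ...
Per-habitat Dice vs ground truth (1.0 = perfect recovery):
  habitat 1: 0.943
  habitat 2: 0.944
  habitat 5: 0.925
  ...
```

The thresholds sit between the phantom's low/high class means; at a 4σ class
separation every concentric habitat is recovered with Dice ≥ 0.92 (1.0 with
zero noise). `examples/02_cohort_tables.py` reproduces the cohort statistics
from the packaged tables (e.g. habitat 7 — edema — occupies a median 34.7% of
tumor volume in IDH-1 wild-type vs 15.4% in mutated tumors, exact Mann-Whitney
p = 0.091), and `examples/03_biopsy_voi.py` shows VOI sampling.

A thin CLI wraps the same API for shell use:

```
gliohab phantom --out-dir ds --n 3 --seed 1
gliohab habitats --manifest ds/manifest.csv --out-dir maps
gliohab stats --from-fixtures --out-dir tables
gliohab voi --targets targets.csv --labels maps/sub-01_habitats.nii.gz --out voi.csv
```

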