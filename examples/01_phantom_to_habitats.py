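"""Generate a synthetic phantom and recover its habitats with the pipeline.

Builds one phantom subject (concentric tumor zones, 4-sigma class separation),
runs the per-map Otsu clustering, and prints the thresholds, the habitat
volume fractions, and the per-habitat Dice overlap against the known truth.
"""

import numpy as np

import gliohab as gh

spec = gh.PhantomSpec(speckle_fraction=0.0)
vp, faza, md, truth = gh.generate_phantom(spec, seed=42)

hmap = gh.compute_habitats(vp, faza, md, truth.flair_mask)

print("Otsu thresholds (map units):")
for mod, info in hmap.provenance["maps"].items():
    print(f"  {mod:>4}: T = {info['threshold']:.4g}  "
          f"({info['n_excluded']} of {info['n_excluded'] + info['n_included']} voxels outlier-excluded)")

row = gh.habitat_fractions(hmap)
print("\nHabitat volume fractions (% of assigned tumor volume):")
for h, f in zip(range(1, 9), row.fractions):
    print(f"  habitat {h}: {f:5.1f}")

print("\nPer-habitat Dice vs ground truth (1.0 = perfect recovery):")
for h in range(1, 9):
    a, b = hmap.label == h, truth.habitat_label == h
    if b.sum():
        print(f"  habitat {h}: {2 * (a & b).sum() / (a.sum() + b.sum()):.3f}")
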