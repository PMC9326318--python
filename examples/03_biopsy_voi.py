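"""Sample a habitat map with 5-mm spherical biopsy VOIs.

Recovers habitats on a phantom, then samples two stereotactic target points
with 5-mm-diameter spheres and prints the prevalence-ordered habitat profile
of each — the same representation used to relate imaging habitats to the
histology of stereotactic biopsy specimens.
"""

import gliohab as gh

spec = gh.PhantomSpec(speckle_fraction=0.0)
vp, faza, md, truth = gh.generate_phantom(spec, seed=7)
hmap = gh.compute_habitats(vp, faza, md, truth.flair_mask)

center = spec.tumor_center
targets = {
    "A (tumor core)": center,
    "B (34 mm lateral, edema halo)": (center[0] + 34.0, center[1], center[2]),
}

for name, point in targets.items():
    voi = gh.sphere_voxels(hmap.grid, point, diameter=5.0)
    prof = gh.voi_habitat_profile(hmap, voi)
    ordered = ", ".join(map(str, prof.ordered_habitats))
    print(f"sample {name}: {voi.n_voxels} voxels, "
          f"habitats by prevalence [{ordered}], "
          f"dominant fraction {prof.dominant_fraction:.2f}")

print("\nHistology table fixture (first biopsy cohort rows):")
t4 = gh.load_fixture("table4")
print(t4.head(5).to_string(index=False))
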