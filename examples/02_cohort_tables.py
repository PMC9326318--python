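"""Cohort statistics from the packaged printed-table fixtures.

Loads the clinical table and the per-patient habitat fraction table, and
reproduces the cohort row averages, the IDH-1 grouped summary, and the
Mann-Whitney comparison of the edema habitat (7) between IDH-1 groups.
"""

import gliohab as gh
from gliohab import habitat_stats as hs
from gliohab.synthetic_data import fraction_frame_from_table2

fractions = fraction_frame_from_table2()   # 17 subjects x 8 habitats, percent
clinical = gh.load_fixture("table1")
clinical.index.name = "subject_id"

avg = hs.cohort_table(fractions)["row_average"]
print("Cohort mean habitat fractions (% of tumor volume):")
print(avg.round(1).to_string())

idh = hs.grouped_summary(fractions, clinical, "idh1")
print("\nHabitat 7 (low perfusion/hypoxia, high diffusivity — vasogenic edema):")
print(f"  IDH-1 wild-type: mean {idh.loc[7, ('wild-type', 'mean')]:.1f}%, "
      f"median {idh.loc[7, ('wild-type', 'median')]:.1f}%  (n={idh.loc[7, ('wild-type', 'n')]:.0f})")
print(f"  IDH-1 mutated:   mean {idh.loc[7, ('mutated', 'mean')]:.1f}%, "
      f"median {idh.loc[7, ('mutated', 'median')]:.1f}%  (n={idh.loc[7, ('mutated', 'n')]:.0f})")

merged = fractions.join(clinical["idh1"])
res = hs.mann_whitney_u(
    merged.loc[merged["idh1"] == "wild-type", 7],
    merged.loc[merged["idh1"] == "mutated", 7],
)
print(f"  Mann-Whitney U = {res.statistic:.0f}, exact two-sided p = {res.p_value:.4f}")

desc = hs.descriptive_cohort(clinical)
print("\nClinical descriptives:")
print(f"  CE-tumor volume:    {desc.loc['ce_volume_cm3', 'mean']:.1f} +/- "
      f"{desc.loc['ce_volume_cm3', 'sd']:.1f} cm^3")
print(f"  FLAIR-tumor volume: {desc.loc['flair_volume_cm3', 'mean']:.1f} +/- "
      f"{desc.loc['flair_volume_cm3', 'sd']:.1f} cm^3")
print(f"  Overall survival:   mean {desc.loc['os_weeks', 'mean']:.1f} wk, "
      f"median {desc.loc['os_weeks', 'median']:.0f} wk "
      f"(range {desc.loc['os_weeks', 'min']:.0f}-{desc.loc['os_weeks', 'max']:.0f})")
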