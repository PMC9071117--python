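"""Generate one reporting cycle's synthetic extracts and peek at them.

The cohort is drawn at the study margins: every patient is in care during
the 12-month window, then realises a Box B/C/D pattern in the 6-month OOC
window, with a known ground-truth disposition for later recovery checks.
"""

from d2care import CohortConfig, simulate_cohort

config = CohortConfig(n_patients=1000, seed=42)
cohort = simulate_cohort(config)

print(f"patients:      {len(cohort.patients)}")
print(f"clinic visits: {len(cohort.visits)}")
print(f"lab events:    {len(cohort.labs)}  "
      f"(VL {int(cohort.labs['kind'].eq('VL').sum())}, "
      f"CD4 {int(cohort.labs['kind'].eq('CD4').sum())})")
print(f"appointments:  {len(cohort.appointments)}")
print()
print("ground-truth box mix (the generator's assignment):")
print(cohort.ground_truth["true_box"].value_counts().sort_index().to_string())
print()
print("ground-truth disposition mix among potentially-OOC patients:")
print(cohort.ground_truth["true_disposition"].value_counts().to_string())
# Box B = VL but no visit, C = visit but no VL, D = neither; the disposition
# mix mirrors the case-conference outcome frequencies of a statewide cycle.
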