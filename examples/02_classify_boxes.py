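"""Reconcile clinic and surveillance extracts and classify Box A/B/C/D.

Writes the extracts to disk, reads them back through the strict flat-file
layer (the same path a health-department cycle uses), joins the two
streams, and classifies every in-care patient by visit/VL presence in the
out-of-care window.
"""

import tempfile
from pathlib import Path

from d2care import CohortConfig, classify_cohort, simulate_cohort, write_cohort
from d2care import io as d2c_io
from d2care.eligibility import box_shares

config = CohortConfig(n_patients=1000, seed=42)
cohort = simulate_cohort(config)

with tempfile.TemporaryDirectory() as tmp:
    paths = write_cohort(cohort, Path(tmp))
    clinic = d2c_io.read_clinic_extract(paths["clinic_visits"],
                                        paths["appointments"])
    labs, rejected = d2c_io.read_surveillance_extract(paths["surveillance_labs"])
    patients = d2c_io.read_patients(paths["patients"])
    joined, exceptions = d2c_io.join_surveillance(clinic.visits, labs, patients)
    print(f"joined rows: {len(joined)}   orphan events: {len(exceptions)}   "
          f"rejected rows: {len(rejected)}")

    boxes = classify_cohort(patients, clinic.visits, labs, config.window)

print()
print("box counts (A is still in care and excluded from the OOC cohort):")
print(boxes["box"].value_counts().sort_index().to_string())
print()
print("shares of the potentially-OOC cohort (percent):", box_shares(boxes["box"]))
# The statewide cycle this emulates found roughly B 25.8 / C 45.4 / D 28.8.
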