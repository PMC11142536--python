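"""Generate a small paired-modality cohort and write it to disk.

Each patient contributes ~21 pathologist-annotated 50-um spots; every spot
yields one profile mass spectrum (700-3500 Da) and one H&E-like RGB patch,
and all of a patient's spots share the patient's diagnosis.
"""

from pathlib import Path

import numpy as np

from melafuse import CohortConfig, generate_cohort, write_cohort

config = CohortConfig(n_patients=10, spots_per_patient_mean=21.0, seed=1)
cohort = generate_cohort(config)

labels = cohort.labels
print(f"patients: {config.n_patients}, spots: {len(cohort.records)}")
print(f"melanoma spots: {(labels == 'melanoma').sum()}, "
      f"nevus spots: {(labels == 'nevus').sum()}")
print(f"spectrum axis: {len(cohort.spectra[0])} bins over "
      f"{cohort.spectra[0].mz[0]:.0f}-{cohort.spectra[0].mz[-1]:.0f} Da")
print(f"patch size: {cohort.patches[0].pixels.shape}")

ims_off = sum(not e.ims_informative for e in cohort.effects)
print(f"IMS-uninformative patients: {ims_off} (class-neutral spectra)")

out = Path("scratch/example_cohort")
write_cohort(cohort, out)
print(f"wrote manifest + spectra CSVs + patch PNGs under {out}/")
# The spot counts vary per patient (truncated Poisson around the mean);
# the two classes are balanced by the default 0.5 prevalence.
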