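"""Run the exclusion cascade on a contaminated synthetic cohort.

Generates longitudinal records with labelled injected errors (height
decreases, implausible values, missing fields, weight outliers), runs the
ordered cleaning cascade, and prints the per-stage accounting alongside
the injected truth.
"""

from abmiref import CleaningConfig, run_pipeline
from abmiref.simulate import CohortConfig, generate_cohort

cfg = CohortConfig(
    n_per_cell=12,
    seed=42,
    frac_height_decrease=0.02,
    frac_implausible=0.01,
    frac_missing=0.05,
    frac_weight_outlier=0.02,
)
records, labels, screening = generate_cohort(cfg)
print(f"generated {len(records)} records / "
      f"{records.subject_id.nunique()} subjects")
print("injected:", labels.category.value_counts().to_dict(), "\n")

cleaned, report = run_pipeline(records, CleaningConfig(), screening)

print("stage                         obs removed  subjects removed")
for s in report.stages:
    print(f"{s.stage:<30s} {s.observations_removed:>10d}  {s.subjects_removed:>10d}")
print(f"\nkept {len(cleaned)} records of "
      f"{cleaned.subject_id.nunique()} subjects")
print(
    "\nDeterministic stages remove exactly the injected height decreases\n"
    "and implausible values; the two +/-2 SD stages trim the distribution\n"
    "tails (about 4-5% of clean data by construction)."
)
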