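"""Generate a small synthetic hair-strand cohort and write it to disk.

Each subject contributes one strand: 660 sampling points across 15 element
channels plus sulfur, with circadian-like periodic dynamics.  Cases carry
attenuated periodic amplitudes in Zn, Cu and Li.
"""

from pathlib import Path

from hairdyn import CohortConfig, generate_cohort, write_cohort

config = CohortConfig(n_subjects=12, case_fraction=0.5, effect_size=0.8, seed=7)
records, profiles = generate_cohort(config)

manifest = write_cohort(records, profiles, Path("scratch/example_cohort"), config)
n_cases = sum(r.is_case for r in records)
print(f"cohort: {len(records)} subjects ({n_cases} cases), "
      f"{profiles[0].n_points} points/strand, "
      f"{len(profiles[0].elements)} element channels")
print(f"manifest written to {manifest}")
# The counts are forced by the config: round(case_fraction * n) cases, and
# every strand covers ~10 mm of hair (~1 month of growth).
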