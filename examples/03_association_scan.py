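"""Feature-wide association scan on a synthetic cohort.

Builds the subjects x features RQA/CRQA table, batch-corrects and z-scores
it, fits one sex- and age-adjusted logistic model per feature, applies
Benjamini-Hochberg FDR across features, and summarizes discoveries per
elemental pathway.
"""

import pandas as pd

from hairdyn import (
    CohortConfig,
    associate,
    batch_correct_and_zscore,
    feature_table,
    forest_summary,
    generate_cohort,
)

config = CohortConfig(n_subjects=80, case_fraction=0.5, effect_size=0.8,
                      n_elements=5, seed=19)
records, profiles = generate_cohort(config)
table = feature_table(profiles, list(config.panel)).features
print(f"feature table: {table.shape[0]} subjects x {table.shape[1]} features")

batches = pd.Series({r.subject_id: r.batch for r in records})
normalized = batch_correct_and_zscore(table, batches)
rows = associate(normalized, records)
print(f"significant at FDR<0.05: {int(rows['significant'].sum())}")

print(forest_summary(rows).head(8).to_string(index=False))
# Pathways touching the perturbed elements (Zn, Cu, Li) should dominate the
# discovery count, and periodicity metrics (det, mean_l, lam) should carry
# negative effects: cases have attenuated periodic dynamics.
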