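"""Replicate-strand QA: feature stability across duplicate hairs.

Generates a second strand per subject sharing the same latent dynamics with
fresh measurement noise, recomputes all RQA/CRQA features for both, and
reports the fraction of features agreeing within +/-10%.
"""

import numpy as np

from hairdyn import (
    CohortConfig,
    feature_table,
    generate_cohort,
    generate_replicate_pair,
    replicate_agreement,
)

config = CohortConfig(n_subjects=5, case_fraction=0.4, seed=42, n_elements=6)
records, profiles = generate_cohort(config)

fractions = []
for i, profile in enumerate(profiles):
    replicate = generate_replicate_pair(profile, seed=500 + i)
    pair = feature_table([profile, replicate], list(config.panel))
    report = replicate_agreement(pair.features.iloc[0], pair.features.iloc[1])
    fractions.append(report.fraction_within_10pct)
    print(f"{profile.subject_id}: {100 * report.fraction_within_10pct:.1f}% of "
          f"{report.n_compared} features within +/-10%; worst: "
          f"{report.worst_offenders.index[0]} "
          f"({report.worst_offenders.iloc[0]:.0f}%)")
print(f"mean fraction within +/-10%: {np.mean(fractions):.3f}")
# High agreement means the dynamical features measure the subject's latent
# elemental rhythm, not the per-strand measurement noise.
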