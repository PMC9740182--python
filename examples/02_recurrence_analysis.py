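"""Recurrence quantification of a single element:sulfur ratio series.

Shows the full single-series path: ratio preprocessing, delay selection by
the first minimum of average mutual information, dimension selection by
false nearest neighbors, fixed-recurrence-rate thresholding, and the
12-feature quantification.
"""

from hairdyn import (
    CohortConfig,
    EmbeddingParams,
    embed,
    generate_cohort,
    quantify,
    recurrence_matrix,
    select_delay,
    select_dimension,
    to_ratio_series,
)

config = CohortConfig(n_subjects=4, case_fraction=0.5, effect_size=0.8, seed=3)
records, profiles = generate_cohort(config)

for record, profile in zip(records[:2], profiles[:2]):
    series = to_ratio_series(profile, "Zn")
    tau = select_delay(series.values, max_tau=20)
    m, warn = select_dimension(series.values, tau)
    states = embed(series.values, EmbeddingParams(tau=tau, m=m))
    rec = recurrence_matrix(states, target_rr=0.10, theiler_window=1)
    f = quantify(rec)
    print(f"{record.subject_id} ({record.diagnosis:7s})  Zn:S  tau={tau} m={m}  "
          f"RR={f.rr:.3f}  DET={f.det:.3f}  L={f.mean_l:.1f}  LAM={f.lam:.3f}")
# DET (fraction of recurrences on diagonal lines) is the periodicity
# readout: attenuated circadian dynamics in cases pull it down while the
# recurrence rate itself stays pinned at 10% by construction.
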