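"""Shared helpers for model-layer tests."""

import numpy as np
import pandas as pd

from hairdyn import SubjectRecord


def make_labeled_table(n=80, n_signal=4, n_null=12, seed=0, effect=1.5):
    """Feature table with informative ("sig*") and pure-noise columns."""
    rng = np.random.default_rng(seed)
    labels = np.array([1] * (n // 2) + [0] * (n - n // 2))
    cols = {}
    for i in range(n_signal):
        cols[f"sig{i}|det"] = labels * effect + rng.normal(size=n)
    for i in range(n_null):
        cols[f"null{i}|rr"] = rng.normal(size=n)
    table = pd.DataFrame(cols, index=[f"S{i:03d}" for i in range(n)])
    subjects = [
        SubjectRecord(subject_id=f"S{i:03d}",
                      diagnosis="case" if labels[i] else "control",
                      sex="male" if rng.random() < 0.5 else "female",
                      age_months=float(rng.uniform(1, 200)),
                      site="site1", batch="site1")
        for i in range(n)
    ]
    return table, subjects
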