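"""Replicate-agreement QA: feature stability across duplicate strands.

Mirrors the laboratory practice of analyzing two hair strands from the same
participant at one time point: the dynamical features of the two strands
should agree closely (the field's working criterion is within +/-10%).
Percent difference uses the symmetric mean denominator
``100 * |f1 - f2| / ((|f1| + |f2|) / 2)``, making the report symmetric in its
arguments and invariant to a common positive rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["AgreementReport", "replicate_agreement"]


@dataclass
class AgreementReport:
    percent_difference: pd.Series  # per feature, NaN where excluded
    fraction_within_10pct: float
    excluded_near_zero: list[str]
    worst_offenders: pd.Series  # top features by percent difference

    @property
    def n_compared(self) -> int:
        return int(self.percent_difference.notna().sum())


def replicate_agreement(features_a: pd.Series | pd.DataFrame,
                        features_b: pd.Series | pd.DataFrame,
                        tolerance_pct: float = 10.0,
                        n_worst: int = 10) -> AgreementReport:
    """Per-feature percent difference between two replicate feature vectors.

    Features where both values are essentially zero (symmetric mean < 1e-9)
    carry no information about relative agreement; they are excluded from
    the denominator and listed.
    """
    a = features_a.squeeze() if isinstance(features_a, pd.DataFrame) else features_a
    b = features_b.squeeze() if isinstance(features_b, pd.DataFrame) else features_b
    if list(a.index) != list(b.index):
        raise ValueError("replicate feature columns do not match")
    a = a.astype(float)
    b = b.astype(float)
    denom = (a.abs() + b.abs()) / 2.0
    near_zero = denom < 1e-9
    pct = 100.0 * (a - b).abs() / denom.mask(near_zero)
    compared = pct.dropna()
    fraction = float((compared <= tolerance_pct).mean()) if len(compared) else 1.0
    return AgreementReport(
        percent_difference=pct,
        fraction_within_10pct=fraction,
        excluded_near_zero=list(a.index[near_zero]),
        worst_offenders=compared.sort_values(ascending=False).head(n_worst),
    )
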