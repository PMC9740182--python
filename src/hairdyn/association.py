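"""Feature-wide association scan: batch correction, z-scoring, per-feature
adjusted logistic models, and false-discovery-rate control.

Each engineered dynamical feature is tested in its own logistic regression
``diagnosis ~ feature + sex + age_months`` (Wald test on the feature
coefficient); the resulting p-values are corrected across all testable
features with Benjamini-Hochberg.  Features are batch-corrected
(location-scale within batch) and z-scored beforehand, so reported effects
are standardized log-odds per SD of feature.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

__all__ = ["batch_correct_and_zscore", "associate", "forest_summary"]

logger = logging.getLogger(__name__)


def _pathway(feature_id: str) -> str:
    return feature_id.split("|")[0]


def _metric(feature_id: str) -> str:
    return feature_id.split("|")[-1]


def batch_correct_and_zscore(table: pd.DataFrame, batches: pd.Series) -> pd.DataFrame:
    """Within-batch centering/scaling to unit variance, then global re-z-scoring.

    ``batches`` is indexed by subject id (table rows).  Every batch needs at
    least 3 subjects; features constant within some batch are set missing
    (with a warning) rather than producing infinities.
    """
    batches = batches.reindex(table.index)
    if batches.isna().any():
        missing = table.index[batches.isna()].tolist()
        raise ValueError(f"subjects without a batch label: {missing}")
    counts = batches.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"batches with fewer than 3 subjects: {sorted(small.index)}")

    grouped = table.groupby(batches, observed=True)
    mean = grouped.transform("mean")
    sd = grouped.transform("std", ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = (table - mean) / sd
    constant = sd.le(0) | sd.isna()
    if constant.to_numpy().any():
        bad = table.columns[constant.any(axis=0)]
        logger.warning("%d features constant within a batch set to missing", len(bad))
        corrected = corrected.mask(constant)

    # Global re-standardization keeps the cross-batch scale interpretable.
    global_sd = corrected.std(ddof=1)
    out = (corrected - corrected.mean()) / global_sd.replace(0, np.nan)
    return out


def _fit_one(y: np.ndarray, design: np.ndarray) -> tuple[float, float, float]:
    """Logistic Wald statistics for column 1 of the design (the feature)."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            model = sm.Logit(y, design)
            fit = model.fit(disp=0, maxiter=100)
        except PerfectSeparationWarning as exc:  # escalated to an exception
            raise PerfectSeparationError(str(exc)) from None
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    if not (np.isfinite(beta) and np.isfinite(se) and se < 1e4):
        raise PerfectSeparationError("non-finite Wald statistics")
    return beta, se, p


def associate(table: pd.DataFrame, subjects, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """One adjusted logistic model per feature, BH-corrected across features.

    Returns a DataFrame with columns feature_id, pathway, metric, beta, se,
    p, q, significant, direction, flagged.  Features with missing values are
    fit on their complete cases; separated or otherwise unstable fits are
    flagged and excluded from the FDR denominator.
    """
    subj = {s.subject_id: s for s in subjects}
    missing = [sid for sid in table.index if sid not in subj]
    if missing:
        raise ValueError(f"subjects missing metadata: {missing}")
    y_all = np.array([1.0 if subj[sid].is_case else 0.0 for sid in table.index])
    if len(np.unique(y_all)) < 2:
        raise ValueError("outcome is single-class; association scan undefined")
    sex = np.array([1.0 if subj[sid].sex == "male" else 0.0 for sid in table.index])
    age = np.array([subj[sid].age_months for sid in table.index])
    age = (age - age.mean()) / (age.std() or 1.0)

    rows = []
    for fid in table.columns:
        x = table[fid].to_numpy(dtype=float)
        ok = np.isfinite(x)
        beta = se = p = np.nan
        flagged = ""
        if ok.sum() < 8 or len(np.unique(y_all[ok])) < 2 or np.ptp(x[ok]) == 0:
            flagged = "degenerate"
        else:
            design = np.column_stack([np.ones(ok.sum()), x[ok], sex[ok], age[ok]])
            try:
                beta, se, p = _fit_one(y_all[ok], design)
            except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
                flagged = "separation"
        rows.append({"feature_id": fid, "pathway": _pathway(fid), "metric": _metric(fid),
                     "beta": beta, "se": se, "p": p, "flagged": flagged})
    out = pd.DataFrame(rows)

    testable = out["flagged"].eq("") & out["p"].notna()
    out["q"] = np.nan
    if testable.any():
        _, q, _, _ = multipletests(out.loc[testable, "p"], method="fdr_bh")
        out.loc[testable, "q"] = q
    out["significant"] = out["q"] < fdr_alpha
    out["direction"] = np.sign(out["beta"]).fillna(0).astype(int)
    return out.sort_values("q", na_position="last").reset_index(drop=True)


def forest_summary(rows: pd.DataFrame, fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Per-pathway summary of the association scan (forest-plot input).

    Returns one row per pathway: number of tested and significant features,
    sign split among significant ones, and the smallest q, sorted by
    significant-feature count.
    """
    def _summary(g: pd.DataFrame) -> pd.Series:
        sig = g[g["significant"]]
        return pd.Series({
            "n_features": len(g),
            "n_significant": len(sig),
            "n_positive": int((sig["direction"] > 0).sum()),
            "n_negative": int((sig["direction"] < 0).sum()),
            "min_q": g["q"].min(),
        })

    summary = (rows.groupby("pathway", observed=True)
               .apply(_summary, include_groups=False)
               .reset_index()
               .sort_values(["n_significant", "min_q"], ascending=[False, True])
               .reset_index(drop=True))
    for col in ("n_features", "n_significant", "n_positive", "n_negative"):
        summary[col] = summary[col].astype(int)
    return summary
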