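"""Quantification of (cross-)recurrence matrices into 12 dynamical features.

The feature set is the canonical recurrence-quantification panel, covering
the prevalence (RR), duration and predictability (DET, L, Lmax, DIV, ENTR),
stability (LAM, TT, Vmax, VENTR) and drift (TREND) of recurrent structure,
plus the DET/RR ratio:

==============  ================================================================
rr              recurrence rate: fraction of (included) cells that are recurrent
det             fraction of recurrent points on diagonal lines of length >= lmin
mean_l          mean diagonal line length (lines >= lmin)
l_max           longest diagonal line
div             divergence, 1 / l_max (0 when no line exists)
entr            Shannon entropy (nats) of the diagonal line-length histogram
lam             fraction of recurrent points on vertical lines of length >= vmin
tt              trapping time: mean vertical line length (lines >= vmin)
v_max           longest vertical line
v_entr          Shannon entropy of the vertical line-length histogram
ratio_det_rr    det / rr (0 when rr == 0)
trend           slope of diagonal-wise recurrence density vs displacement
==============  ================================================================

Degenerate matrices produce degenerate values (zeros), never errors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, asdict, fields

import numpy as np
import pandas as pd

from .embedding import EmbeddingParams, embed, select_delay, select_dimension
from .recurrence import RecurrenceResult, cross_recurrence_matrix, recurrence_matrix
from .strand_io import ratio_frame

__all__ = [
    "RqaFeatureSet",
    "METRIC_NAMES",
    "quantify",
    "diagonal_line_lengths",
    "vertical_line_lengths",
    "feature_table",
    "FeatureTableResult",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "rr", "det", "mean_l", "l_max", "div", "entr",
    "lam", "tt", "v_max", "v_entr", "ratio_det_rr", "trend",
)


@dataclass(frozen=True)
class RqaFeatureSet:
    rr: float
    det: float
    mean_l: float
    l_max: int
    div: float
    entr: float
    lam: float
    tt: float
    v_max: int
    v_entr: float
    ratio_det_rr: float
    trend: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _run_lengths(flat: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a 0/1 vector (0-separated)."""
    padded = np.concatenate(([0], flat, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return ends - starts


def diagonal_line_lengths(matrix: np.ndarray) -> np.ndarray:
    """All maximal diagonal line lengths of a binary matrix.

    Implemented via a shear: row i of the N x M matrix is written at column
    offset i of a zero-padded buffer, which turns diagonals into columns; a
    single run-length pass over the flattened buffer then yields every
    diagonal line.
    """
    m = np.ascontiguousarray(matrix, dtype=np.uint8)
    n_rows, n_cols = m.shape
    sheared = np.zeros((n_rows, n_cols + n_rows), dtype=np.uint8)
    cols = np.arange(n_cols)
    for i in range(n_rows):
        sheared[i, (n_rows - 1 - i) + cols] = m[i]
    # Flatten column-major with a zero row separating consecutive columns.
    buffered = np.vstack([sheared, np.zeros(sheared.shape[1], dtype=np.uint8)])
    return _run_lengths(buffered.T.ravel())


def vertical_line_lengths(matrix: np.ndarray) -> np.ndarray:
    """All maximal vertical line lengths of a binary matrix."""
    m = np.ascontiguousarray(matrix, dtype=np.uint8)
    buffered = np.vstack([m, np.zeros(m.shape[1], dtype=np.uint8)])
    return _run_lengths(buffered.T.ravel())


def _entropy(lengths: np.ndarray) -> float:
    if len(lengths) == 0:
        return 0.0
    _, counts = np.unique(lengths, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def _trend(matrix: np.ndarray, theiler_window: int, min_cells: int = 10) -> float:
    """Least-squares slope of recurrence density over diagonal displacement.

    Uses upper-triangle diagonals with at least ``min_cells`` cells, starting
    outside the Theiler window; symmetric matrices carry the same information
    below the diagonal.
    """
    n_rows, n_cols = matrix.shape
    n = min(n_rows, n_cols)
    start = max(theiler_window, 1)
    offsets = np.arange(start, n - min_cells + 1)
    if len(offsets) < 2:
        return 0.0
    rows, cols = np.nonzero(matrix)
    d = cols - rows
    counts = np.bincount(d[(d >= start) & (d <= offsets[-1])] - start,
                         minlength=len(offsets))
    lengths = np.minimum(n_rows, n_cols - offsets)
    density = counts / lengths
    slope = np.polyfit(offsets, density, 1)[0]
    return float(slope)


def quantify(result: RecurrenceResult, lmin: int = 2, vmin: int = 2) -> RqaFeatureSet:
    """Compute the 12-feature RQA/CRQA panel from one recurrence matrix."""
    matrix = result.matrix
    n_recurrent = int(matrix.sum())
    rr = result.achieved_rr

    # With the default Theiler window (1) the line of identity is already
    # zeroed out of an auto-recurrence matrix, so diagonal lines never
    # include the trivial self-match; at window 0 the LOI is counted, which
    # keeps quantify(cross(x, x)) identical to quantify(auto(x, window=0)).
    diag = diagonal_line_lengths(matrix)
    long_diag = diag[diag >= lmin]
    diag_points = int(long_diag.sum())
    det = diag_points / n_recurrent if n_recurrent else 0.0
    mean_l = float(long_diag.mean()) if len(long_diag) else 0.0
    l_max = int(long_diag.max()) if len(long_diag) else 0
    div = 1.0 / l_max if l_max >= 1 else 0.0
    entr = _entropy(long_diag)

    vert = vertical_line_lengths(matrix)
    long_vert = vert[vert >= vmin]
    lam = int(long_vert.sum()) / n_recurrent if n_recurrent else 0.0
    tt = float(long_vert.mean()) if len(long_vert) else 0.0
    v_max = int(long_vert.max()) if len(long_vert) else 0
    v_entr = _entropy(long_vert)

    return RqaFeatureSet(
        rr=rr,
        det=float(det),
        mean_l=mean_l,
        l_max=l_max,
        div=float(div),
        entr=entr,
        lam=float(lam),
        tt=tt,
        v_max=v_max,
        v_entr=v_entr,
        ratio_det_rr=float(det / rr) if rr > 0 else 0.0,
        trend=_trend(matrix, result.theiler_window),
    )


@dataclass
class FeatureTableResult:
    """Subjects x features matrix with per-feature provenance.

    ``features`` columns are named ``<pathway>|<metric>`` where pathway is a
    single element ("Zn") or an unordered pair ("Cu-Zn"); ``provenance``
    records the embedding parameters and warning flags behind each pathway;
    ``excluded`` lists subjects dropped for excessive feature failures.
    """

    features: pd.DataFrame
    provenance: pd.DataFrame
    excluded: list[str]


def _pathway_features(ratios: pd.DataFrame, panel: list[str], target_rr: float,
                      lmin: int, vmin: int, theiler_window: int,
                      max_tau: int, max_m: int, rtol: float, atol: float,
                      fnn_threshold: float) -> tuple[dict, list[dict]]:
    """All RQA + CRQA features for one subject; returns (row, provenance)."""
    row: dict[str, float] = {}
    prov: list[dict] = []
    params: dict[str, EmbeddingParams | None] = {}
    states: dict[str, np.ndarray] = {}

    for el in panel:
        x = ratios[el].to_numpy()
        try:
            tau = select_delay(x, max_tau=max_tau)
            m, warn = select_dimension(x, tau, max_m=max_m, rtol=rtol, atol=atol,
                                       fnn_threshold=fnn_threshold)
            p = EmbeddingParams(tau=tau, m=m, theiler_window=theiler_window,
                                fnn_warning=warn)
            params[el] = p
            states[el] = embed(x, p)
            rec = recurrence_matrix(states[el], target_rr=target_rr,
                                    theiler_window=theiler_window, params=p)
            feats = quantify(rec, lmin=lmin, vmin=vmin).as_dict()
            reason = ""
        except (ValueError, KeyError) as exc:
            params[el] = None
            feats = {name: np.nan for name in METRIC_NAMES}
            reason = str(exc)
        for name, value in feats.items():
            row[f"{el}|{name}"] = value
        prov.append({
            "pathway": el, "kind": "auto",
            "tau_a": params[el].tau if params[el] else np.nan,
            "m": params[el].m if params[el] else np.nan,
            "tau_b": np.nan,
            "fnn_warning": bool(params[el].fnn_warning) if params[el] else False,
            "failure": reason,
        })

    for el_a, el_b in itertools.combinations(panel, 2):
        pathway = f"{el_a}-{el_b}"
        pa, pb = params[el_a], params[el_b]
        try:
            if pa is None or pb is None:
                raise ValueError("embedding failed for one series of the pair")
            # Shared phase-space dimension: each series keeps its own delay,
            # both re-embedded at m = max(m_a, m_b).
            m = max(pa.m, pb.m)
            ea = embed(ratios[el_a].to_numpy(), EmbeddingParams(tau=pa.tau, m=m))
            eb = embed(ratios[el_b].to_numpy(), EmbeddingParams(tau=pb.tau, m=m))
            rec = cross_recurrence_matrix(ea, eb, target_rr=target_rr,
                                          params_a=pa, params_b=pb)
            feats = quantify(rec, lmin=lmin, vmin=vmin).as_dict()
            reason = ""
        except ValueError as exc:
            feats = {name: np.nan for name in METRIC_NAMES}
            reason = str(exc)
        for name, value in feats.items():
            row[f"{pathway}|{name}"] = value
        prov.append({
            "pathway": pathway, "kind": "cross",
            "tau_a": pa.tau if pa else np.nan,
            "m": max(pa.m, pb.m) if (pa and pb) else np.nan,
            "tau_b": pb.tau if pb else np.nan,
            "fnn_warning": False,
            "failure": reason,
        })
    return row, prov


def feature_table(profiles, panel: list[str] | None = None, *,
                  target_rr: float = 0.10, lmin: int = 2, vmin: int = 2,
                  theiler_window: int = 1, max_tau: int = 20, max_m: int = 10,
                  rtol: float = 10.0, atol: float = 2.0,
                  fnn_threshold: float = 0.05,
                  max_failed_fraction: float = 0.20) -> FeatureTableResult:
    """RQA/CRQA feature matrix for a cohort of strands.

    For a p-element panel each subject yields p auto-recurrence matrices and
    p(p-1)/2 cross-recurrence matrices, 12 features each (15 elements ->
    120 matrices -> 1,440 features).  Subjects whose failed-feature fraction
    exceeds ``max_failed_fraction`` are excluded with a warning.
    """
    panel = list(panel) if panel is not None else list(profiles[0].elements)
    rows: list[dict[str, float]] = []
    index: list[str] = []
    prov_frames: list[pd.DataFrame] = []
    excluded: list[str] = []
    for profile in profiles:
        ratios = ratio_frame(profile, panel)
        row, prov = _pathway_features(
            ratios, panel, target_rr, lmin, vmin, theiler_window,
            max_tau, max_m, rtol, atol, fnn_threshold,
        )
        values = np.array(list(row.values()), dtype=float)
        failed_fraction = np.isnan(values).mean()
        if failed_fraction > max_failed_fraction:
            logger.warning("subject %s excluded: %.0f%% of features failed",
                           profile.subject_id, 100 * failed_fraction)
            excluded.append(profile.subject_id)
            continue
        rows.append(row)
        index.append(profile.subject_id)
        prov_df = pd.DataFrame(prov)
        prov_df.insert(0, "subject_id", profile.subject_id)
        prov_frames.append(prov_df)
    features = pd.DataFrame(rows, index=index)
    features.index.name = "subject_id"
    provenance = pd.concat(prov_frames, ignore_index=True) if prov_frames else pd.DataFrame()
    return FeatureTableResult(features=features, provenance=provenance, excluded=excluded)


def feature_pathway(feature_id: str) -> str:
    return feature_id.split("|")[0]


def feature_metric(feature_id: str) -> str:
    return feature_id.split("|")[1]
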