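"""Recurrence and cross-recurrence matrices at a fixed recurrence rate.

The distance threshold epsilon is not a free parameter: it is set per matrix
to the quantile of the included pairwise Euclidean distances that yields a
target recurrence rate (10% by default), so recurrence structure is
comparable across subjects and elements regardless of signal scale.

Theiler convention: cells with ``|i - j| < theiler_window`` are excluded from
both the epsilon calibration and the matrix, so ``theiler_window=1`` removes
exactly the line of identity and ``theiler_window=0`` removes nothing.
Cross-recurrence uses no Theiler exclusion (no diagonal is privileged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .embedding import EmbeddingParams

__all__ = ["RecurrenceResult", "recurrence_matrix", "cross_recurrence_matrix"]


@dataclass(frozen=True)
class RecurrenceResult:
    matrix: np.ndarray  # uint8 N x M, entries in {0, 1}
    epsilon: float
    achieved_rr: float
    kind: str  # "auto" | "cross"
    theiler_window: int = 0
    params_a: EmbeddingParams | None = None
    params_b: EmbeddingParams | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_text(self) -> str:
        """Plain 0/1 text grid (one matrix row per line) for visual inspection."""
        return "\n".join("".join(map(str, row)) for row in self.matrix)


def _threshold(distances: np.ndarray, target_rr: float) -> float:
    """Largest epsilon whose recurrence rate does not exceed target_rr.

    Epsilon is the k-th smallest included distance with
    k = floor(target_rr * n_included); ``dist <= eps`` then marks exactly k
    cells recurrent (up to ties).
    """
    flat = distances.ravel()
    if not flat.max() > 0:
        raise ValueError("all state-space distances are zero (constant series)")
    k = int(np.floor(target_rr * flat.size))
    if k < 1:
        raise ValueError(f"target_rr={target_rr} marks no cells recurrent")
    return float(np.partition(flat, k - 1)[k - 1])


def recurrence_matrix(states: np.ndarray, target_rr: float = 0.10,
                      theiler_window: int = 1,
                      params: EmbeddingParams | None = None) -> RecurrenceResult:
    """Auto-recurrence matrix of one embedded series at a fixed recurrence rate."""
    states = np.atleast_2d(np.asarray(states, dtype=float))
    if states.shape[0] < 10:
        raise ValueError(f"need >= 10 embedded states, got {states.shape[0]}")
    n = states.shape[0]
    dist = cdist(states, states)
    offsets = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    included = offsets >= theiler_window
    if not included.any():
        raise ValueError(f"theiler_window={theiler_window} excludes every cell")
    if target_rr >= 1.0:
        eps = float(dist[included].max())
    else:
        eps = _threshold(dist[included], target_rr)
    matrix = ((dist <= eps) & included).astype(np.uint8)
    achieved = float(matrix.sum() / included.sum())
    return RecurrenceResult(matrix=matrix, epsilon=eps, achieved_rr=achieved,
                            kind="auto", theiler_window=theiler_window,
                            params_a=params)


def cross_recurrence_matrix(states_a: np.ndarray, states_b: np.ndarray,
                            target_rr: float = 0.10,
                            params_a: EmbeddingParams | None = None,
                            params_b: EmbeddingParams | None = None) -> RecurrenceResult:
    """Cross-recurrence matrix of two series embedded in a common dimension."""
    a = np.atleast_2d(np.asarray(states_a, dtype=float))
    b = np.atleast_2d(np.asarray(states_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"embedding dimensions differ ({a.shape[1]} vs {b.shape[1]}); "
            "re-embed both series in a shared dimension first"
        )
    if min(a.shape[0], b.shape[0]) < 10:
        raise ValueError("need >= 10 embedded states in each series")
    dist = cdist(a, b)
    if target_rr >= 1.0:
        eps = float(dist.max())
    else:
        eps = _threshold(dist, target_rr)
    matrix = (dist <= eps).astype(np.uint8)
    achieved = float(matrix.mean())
    return RecurrenceResult(matrix=matrix, epsilon=eps, achieved_rr=achieved,
                            kind="cross", theiler_window=0,
                            params_a=params_a, params_b=params_b)
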