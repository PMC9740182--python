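"""Delay-embedding parameter selection and state-space reconstruction.

The scalar series x(t) is lifted to state vectors
(x_t, x_{t+tau}, ..., x_{t+(m-1)tau}).  The delay tau is chosen at the first
local minimum of the average mutual information AMI(tau); the dimension m by
Kennel's false-nearest-neighbor criterion.  Both estimators are invariant to
affine transforms of the series: AMI uses an equal-width 2-D histogram whose
bins track the data range, and FNN uses relative distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "EmbeddingParams",
    "average_mutual_information",
    "select_delay",
    "fnn_fractions",
    "select_dimension",
    "embed",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Embedding delay/dimension and the Theiler window used downstream."""

    tau: int
    m: int
    theiler_window: int = 1
    fnn_warning: bool = False  # set when FNN never crossed its acceptance level

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.theiler_window < 0:
            raise ValueError("theiler_window must be >= 0")

    def embedded_length(self, n_points: int) -> int:
        return n_points - (self.m - 1) * self.tau


def _ami_bins(n: int) -> int:
    # Equal-width binning; sqrt(n/5) keeps ~5 pairs per bin on average.
    return min(64, int(np.ceil(np.sqrt(n / 5))))


def _normal_scores(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm, rankdata

    ranks = rankdata(x) / (len(x) + 1)
    return norm.ppf(ranks)


def average_mutual_information(values: np.ndarray, tau: int,
                               estimator: str = "copula",
                               bins: int | None = None) -> float:
    """AMI (nats) between x(t) and x(t+tau).

    ``estimator="copula"`` (default) is a Gaussian-copula estimate,
    ``-0.5 * log(1 - rho^2)`` with rho the correlation of the pair's normal
    scores: rank-based, hence exactly invariant to monotone transforms, and
    smooth in tau (an equal-width 2-D histogram estimate fluctuates strongly
    with tau on near-periodic signals, which corrupts the first-minimum
    rule).  ``estimator="histogram"`` gives the classic binned estimate.
    """
    x = np.asarray(values, dtype=float)
    if tau < 1 or tau >= len(x):
        raise ValueError(f"tau={tau} out of range for series of length {len(x)}")
    a, b = x[:-tau], x[tau:]
    if estimator == "copula":
        z = _normal_scores(x)
        rho = np.clip(np.corrcoef(z[:-tau], z[tau:])[0, 1], -0.999999, 0.999999)
        return float(-0.5 * np.log1p(-rho**2))
    if estimator == "histogram":
        if bins is None:
            bins = _ami_bins(len(x))
        joint, _, _ = np.histogram2d(a, b, bins=bins)
        pxy = joint / joint.sum()
        px = pxy.sum(axis=1, keepdims=True)
        py = pxy.sum(axis=0, keepdims=True)
        nz = pxy > 0
        return float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))
    raise ValueError(f"unknown AMI estimator {estimator!r}")


def select_delay(values: np.ndarray, max_tau: int = 20,
                 estimator: str = "copula") -> int:
    """First local minimum of AMI(tau) over tau = 1..max_tau.

    Falls back to the argmin over the scanned range when no local minimum
    exists.  Errors on constant series (AMI undefined) and on series shorter
    than 4*max_tau.
    """
    x = np.asarray(values, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("constant series: mutual information is undefined")
    if len(x) < 4 * max_tau:
        raise ValueError(f"series of length {len(x)} too short for max_tau={max_tau} "
                         f"(need >= {4 * max_tau})")
    if estimator == "copula":
        z = _normal_scores(x)
        rho = np.array([np.corrcoef(z[:-tau], z[tau:])[0, 1] for tau in range(1, max_tau + 1)])
        ami = -0.5 * np.log1p(-np.clip(rho, -0.999999, 0.999999) ** 2)
    else:
        ami = np.array([average_mutual_information(x, tau, estimator=estimator)
                        for tau in range(1, max_tau + 1)])
    for i in range(1, len(ami) - 1):
        if ami[i] < ami[i - 1] and ami[i] <= ami[i + 1]:
            return i + 1
    return int(np.argmin(ami)) + 1


def fnn_fractions(values: np.ndarray, tau: int, max_m: int = 10,
                  rtol: float = 10.0, atol: float = 2.0) -> np.ndarray:
    """False-nearest-neighbor fraction for m = 1..max_m (Kennel criterion).

    A neighbor pair (i, j), nearest in dimension m, is "false" when the extra
    coordinate revealed at dimension m+1 either stretches the pair by more
    than ``rtol`` relative to its m-dimensional distance, or moves it by more
    than ``atol`` standard deviations of the series.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("constant series: FNN undefined")
    fractions = np.empty(max_m)
    for m in range(1, max_m + 1):
        n_next = len(x) - m * tau  # points that survive embedding at m+1
        if n_next < 2:
            raise ValueError(f"series too short for FNN at m={m}, tau={tau}")
        emb = embed(x, EmbeddingParams(tau=tau, m=m))[:n_next]
        extra = x[m * tau: m * tau + n_next]
        tree = cKDTree(emb)
        dist, idx = tree.query(emb, k=2)
        rd, nn = dist[:, 1], idx[:, 1]
        gap = np.abs(extra - extra[nn])
        # Below ~machine precision the stretch ratio gap/rd is meaningless
        # (periodic signals produce exact revisits); such pairs are judged by
        # the absolute criterion alone.
        floor = 1e-8 * sd
        with np.errstate(divide="ignore", invalid="ignore"):
            stretch = np.divide(gap, rd, out=np.zeros_like(gap), where=rd > floor)
        stretch[(rd <= floor) & (gap > floor)] = np.inf
        false = (stretch > rtol) | (np.sqrt(rd**2 + gap**2) / sd > atol)
        fractions[m - 1] = false.mean()
    return fractions


def select_dimension(values: np.ndarray, tau: int, max_m: int = 10,
                     rtol: float = 10.0, atol: float = 2.0,
                     fnn_threshold: float = 0.05) -> tuple[int, bool]:
    """Smallest m whose FNN fraction drops below ``fnn_threshold``.

    Returns ``(m, warning)``; ``warning`` is True when no m in 1..max_m
    reaches the threshold, in which case m = max_m.
    """
    fractions = fnn_fractions(values, tau, max_m=max_m, rtol=rtol, atol=atol)
    below = np.flatnonzero(fractions < fnn_threshold)
    if len(below):
        return int(below[0]) + 1, False
    return max_m, True


def embed(values: np.ndarray, params: EmbeddingParams) -> np.ndarray:
    """Delay-embed: row i = (x[i], x[i+tau], ..., x[i+(m-1)tau])."""
    x = np.asarray(values, dtype=float)
    n_emb = params.embedded_length(len(x))
    if n_emb < 1:
        raise ValueError(
            f"series of length {len(x)} too short for m={params.m}, tau={params.tau}"
        )
    cols = [x[k * params.tau: k * params.tau + n_emb] for k in range(params.m)]
    return np.column_stack(cols)
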