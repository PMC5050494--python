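"""Molecular counting from photoswitching (blinking) kinetics.

A photoswitchable fluorophore cycles between a dark and an emitting state
until it photobleaches.  Under a Markov-chain model of this process the
number of *re*-activations N of a single fluorophore is geometric with
blinking probability q:  P(N | 1, q) = q^N (1 − q).  A complex carrying m
independent fluorophores therefore shows a negative-binomial blink count,

    P(N | m, q) = C(N + m − 1, N) · q^N · (1 − q)^m,

so the observed blink-count distribution of many complexes encodes the
oligomeric state m.  The workflow is:

1. :func:`extract_blink_counts` — group localizations into candidate
   molecules (DBSCAN in space), merge each group's frames into on-events
   (gaps <= ``dark_tolerance`` frames fuse) and count N = events − 1.
2. :func:`calibrate_q` — maximum-likelihood q from a known-monomer sample.
3. :func:`fit_oligomer` — exhaustive likelihood scan over candidate m,
   optionally accounting for incomplete labeling p_label < 1 via a
   zero-truncated binomial mixture over the number of active labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import binom, nbinom

from .clustering import dbscan
from .exceptions import EstimationError
from .locdata import LocalizationTable


@dataclass
class BlinkCountDistribution:
    """Histogram of blinking events per molecule/complex.

    ``counts[k]`` is the number of groups observed with N = k
    re-activations; ``n_molecules_observed`` is its total.
    """

    counts: np.ndarray
    extraction_params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be >= 0")

    @classmethod
    def from_events(cls, n_events: np.ndarray, **params) -> "BlinkCountDistribution":
        n_events = np.asarray(n_events, dtype=int)
        counts = np.bincount(n_events) if len(n_events) else np.zeros(1, dtype=int)
        return cls(counts, extraction_params=params)

    @property
    def n_molecules_observed(self) -> int:
        return int(self.counts.sum())

    @property
    def mean(self) -> float:
        n = np.arange(len(self.counts))
        return float((n * self.counts).sum() / self.counts.sum())


def merge_on_events(frames: np.ndarray, dark_tolerance: int = 1) -> int:
    """Number of on-events in a sorted-or-not frame list.

    Consecutive frames, and gaps of at most ``dark_tolerance`` frames,
    belong to the same on-event (this absorbs events split in two by the
    localization software).
    """
    frames = np.unique(np.asarray(frames, dtype=int))
    if not len(frames):
        return 0
    return int(1 + np.sum(np.diff(frames) > dark_tolerance + 1))


def extract_blink_counts(table: LocalizationTable, eps: float, min_pts: int,
                         dark_tolerance: int = 1) -> BlinkCountDistribution:
    """Blink-count histogram from a localization table.

    Spatial DBSCAN(eps, min_pts) defines the candidate molecules/complexes;
    within each cluster the frame indices are merged into on-events and
    N = (on-events − 1) is the group's blink count.  Raises
    :class:`EstimationError` when no cluster is found.
    """
    result = dbscan(table, eps=eps, min_pts=min_pts)
    if result.n_clusters == 0:
        raise EstimationError("no spatial groups found; relax eps/min_pts")
    frames = table.frames
    n_events = []
    for cid in range(result.n_clusters):
        events = merge_on_events(frames[result.labels == cid], dark_tolerance)
        n_events.append(max(events - 1, 0))
    return BlinkCountDistribution.from_events(
        np.asarray(n_events), eps=eps, min_pts=min_pts, dark_tolerance=dark_tolerance)


# ---------------------------------------------------------------------------
# negative-binomial blink model
# ---------------------------------------------------------------------------

def nbinom_pmf(n: int, m: int, q: float):
    """P(N = n | m fluorophores, blinking probability q).

    Sum of m independent geometric re-activation counts:
    C(n+m−1, n) q^n (1−q)^m.  Vectorized over ``n``.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 <= q < 1):
        raise ValueError("q must lie in [0, 1)")
    # scipy's nbinom counts failures before the m-th success with success
    # probability 1−q, which is exactly this distribution
    return nbinom.pmf(n, m, 1.0 - q)


def calibrate_q(monomer_counts: BlinkCountDistribution) -> float:
    """Maximum-likelihood blinking probability from a monomeric standard.

    Under m = 1 the counts are geometric and the MLE has the closed form
    q̂ = N̄ / (1 + N̄) with N̄ the sample mean blink count.
    """
    if monomer_counts.n_molecules_observed == 0:
        raise ValueError("empty blink-count histogram")
    mean = monomer_counts.mean
    return float(mean / (1.0 + mean))


@dataclass
class OligomerFit:
    """Result of the oligomeric-state likelihood scan.

    ``model_table`` maps each candidate m to its maximized log-likelihood
    (and fitted q when q was free); ``m_hat`` is the argmax.
    """

    m_hat: int
    q_hat: float
    p_label: float
    log_likelihood: float
    model_table: dict
    q_free: bool


def _mixture_pmf(n: np.ndarray, m: int, q: float, p_label: float) -> np.ndarray:
    """Blink-count pmf of an m-mer with labeling efficiency p_label.

    The number of active labels k is Binomial(m, p_label) truncated to
    k >= 1 (a complex with zero active labels is never observed), and each
    k contributes a negative-binomial component:
    P(N) = Σ_k w_k · P(N | k, q).
    """
    if not (0 < p_label <= 1):
        raise ValueError("p_label must lie in (0, 1]")
    ks = np.arange(1, m + 1)
    w = binom.pmf(ks, m, p_label)
    w = w / w.sum()
    return sum(wk * nbinom_pmf(n, int(k), q) for k, wk in zip(ks, w))


def _loglik(counts: np.ndarray, m: int, q: float, p_label: float) -> float:
    n = np.arange(len(counts))
    pmf = np.maximum(_mixture_pmf(n, m, q, p_label), 1e-300)
    return float((counts * np.log(pmf)).sum())


def fit_oligomer(dist: BlinkCountDistribution, q: float | None = None,
                 p_label: float = 1.0,
                 m_candidates=range(1, 9)) -> OligomerFit:
    """Oligomeric state by exhaustive likelihood scan over candidate m.

    ``q=None`` profiles the blinking probability per candidate (bounded
    scalar likelihood maximization); a fixed ``q`` — typically from
    :func:`calibrate_q` on a monomer standard — is used as-is.  With
    ``p_label=1`` the model is the plain negative binomial; below 1 the
    zero-truncated label-number mixture is used.
    """
    m_candidates = sorted(set(int(m) for m in m_candidates))
    if not m_candidates or m_candidates[0] < 1:
        raise ValueError("m_candidates must be non-empty integers >= 1")
    counts = dist.counts
    if counts.sum() == 0:
        raise ValueError("empty blink-count histogram")
    q_free = q is None
    degenerate = np.count_nonzero(counts) == 1
    if q_free and degenerate:
        import warnings
        warnings.warn("single-bin histogram: profiled q is at the boundary")

    table = {}
    for m in m_candidates:
        if q_free:
            res = minimize_scalar(lambda qq: -_loglik(counts, m, qq, p_label),
                                  bounds=(1e-9, 1 - 1e-9), method="bounded")
            table[m] = {"loglik": -float(res.fun), "q": float(res.x)}
        else:
            table[m] = {"loglik": _loglik(counts, m, q, p_label), "q": float(q)}
    m_hat = max(table, key=lambda m: table[m]["loglik"])
    return OligomerFit(m_hat=m_hat, q_hat=table[m_hat]["q"], p_label=p_label,
                       log_likelihood=table[m_hat]["loglik"], model_table=table,
                       q_free=q_free)
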