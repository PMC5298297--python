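"""Symmetric flip-error estimation from replicated screening outcomes.

Assume each binary screening measurement reports the opposite of the truth
with probability e (the same for false positives and false negatives), and
that a fraction p of tested compound-target pairs is truly active.  Among
pairs measured in exactly two independent assays:

    P(disagree)     = 2 e (1 - e)
    P(both active)  = p (1 - e)^2 + (1 - p) e^2

which invert in closed form: with d the observed disagreement fraction and a
the agree-active fraction,

    e = (1 - sqrt(1 - 2 d)) / 2          (smaller root, e <= 1/2)
    p = (a - e^2) / (1 - 2 e)

The positive predictive value of a single observed active outcome follows as
ppv = p (1 - e) / (p (1 - e) + (1 - p) e).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .store import ReplicatePairCounts

logger = logging.getLogger(__name__)

__all__ = ["ErrorEstimate", "ErrorRateEstimator", "estimate_error",
           "expected_pair_counts", "simulate_replicate_pairs"]


@dataclass
class ErrorEstimate:
    e: float    # per-outcome flip probability
    p: float    # true-active fraction among tested pairs
    ppv: float  # fraction of observed actives that are true actives
    n_pairs: float

    def __post_init__(self):
        if not (0.0 <= self.e <= 0.5):
            raise ValueError("e must lie in [0, 0.5]")
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.ppv <= 1.0):
            raise ValueError("p and ppv must lie in [0, 1]")


def _solve(counts: ReplicatePairCounts) -> ErrorEstimate:
    total = counts.total
    if total <= 0:
        raise ValueError("no exactly-twice replicate pairs")
    d = counts.n_disagree / total
    if d >= 0.5:
        raise ValueError(
            f"disagreement fraction {d:.3f} >= 0.5 violates the symmetric "
            "error model (no real root)")
    e = (1.0 - math.sqrt(1.0 - 2.0 * d)) / 2.0
    a = counts.n_agree_active / total
    if e < 0.5:
        p = (a - e * e) / (1.0 - 2.0 * e)
    else:  # pragma: no cover - excluded by d < 0.5
        p = a
    if p < 0.0:
        logger.warning("implied true-active fraction %.3g < 0; clamped to 0", p)
        p = 0.0
    p = min(p, 1.0)
    denom = p * (1.0 - e) + (1.0 - p) * e
    ppv = p * (1.0 - e) / denom if denom > 0 else 1.0
    return ErrorEstimate(e=e, p=p, ppv=ppv, n_pairs=total)


def estimate_error(counts: ReplicatePairCounts) -> ErrorEstimate:
    """Closed-form (e, p, ppv) from exactly-twice replicate agreement counts."""
    return _solve(counts)


class ErrorRateEstimator(BaseEstimator):
    """Estimator wrapper around the closed-form replicate error solution.

    After :meth:`fit`, exposes ``e_``, ``p_``, ``ppv_`` and ``n_pairs_``.
    """

    def fit(self, counts: ReplicatePairCounts, y=None):
        est = _solve(counts)
        self.e_ = est.e
        self.p_ = est.p
        self.ppv_ = est.ppv
        self.n_pairs_ = est.n_pairs
        return self

    @property
    def estimate_(self) -> ErrorEstimate:
        return ErrorEstimate(self.e_, self.p_, self.ppv_, self.n_pairs_)


def expected_pair_counts(e: float, p: float, total: float = 1.0) -> ReplicatePairCounts:
    """Expected exactly-twice agreement counts under the model; the algebraic
    inverse of :func:`estimate_error`."""
    if not (0.0 <= e < 0.5 and 0.0 <= p <= 1.0):
        raise ValueError("require 0 <= e < 0.5 and 0 <= p <= 1")
    disagree = 2.0 * e * (1.0 - e)
    agree_active = p * (1.0 - e) ** 2 + (1.0 - p) * e ** 2
    agree_inactive = 1.0 - disagree - agree_active
    return ReplicatePairCounts(
        n_agree_active=agree_active * total,
        n_agree_inactive=agree_inactive * total,
        n_disagree=disagree * total,
    )


def simulate_replicate_pairs(
    e: float, p: float, n_pairs: int, seed: int = 0
) -> ReplicatePairCounts:
    """Monte-Carlo draw of ``n_pairs`` twice-measured pairs at (e, p)."""
    rng = np.random.default_rng(seed)
    truth = rng.random(n_pairs) < p
    obs1 = truth ^ (rng.random(n_pairs) < e)
    obs2 = truth ^ (rng.random(n_pairs) < e)
    disagree = obs1 != obs2
    agree_active = (~disagree) & obs1
    agree_inactive = (~disagree) & ~obs1
    return ReplicatePairCounts(
        n_agree_active=int(agree_active.sum()),
        n_agree_inactive=int(agree_inactive.sum()),
        n_disagree=int(disagree.sum()),
    )
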