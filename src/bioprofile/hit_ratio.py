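"""Beta-binomial Bayesian hit-ratio model and promiscuity scoring.

A compound's hit ratio theta is the expected fraction of screened protein
targets it would be active against.  With n actives out of N screened targets
modelled as Binomial(N, theta) and a Beta(alpha, beta) conjugate prior, the
posterior is Beta(alpha + n, beta + N - n).  The prior shapes come from the
method of moments applied to the empirical hit ratios of well-screened active
compounds:

    alpha = mu^2 ((1 - mu) / sigma^2 - 1 / mu)
    beta  = alpha (1 / mu - 1)

A compound's promiscuity probability is the posterior tail mass
P(theta >= 0.25).  Pooled "mixture" samples (equal draws per compound,
subsampled without replacement) compare hit-ratio distributions across
compound sets, e.g. via the two-sample Kolmogorov-Smirnov distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .selectivity import SelectivityProfile

logger = logging.getLogger(__name__)

DEFAULT_PROMISCUITY_THRESHOLD = 0.25
DEFAULT_CUTOFFS = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
                   0.6, 0.7, 0.8, 0.9, 0.99, 0.999, 0.9999)


@dataclass
class BetaPrior:
    alpha: float
    beta: float
    mu: float
    sigma: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("prior shapes must be positive")

    @property
    def dist(self):
        return stats.beta(self.alpha, self.beta)


@dataclass
class HitRatioPosterior:
    compound_id: str
    n: int
    N: int
    alpha_post: float
    beta_post: float

    def __post_init__(self):
        if not (0 <= self.n <= self.N):
            raise ValueError("require 0 <= n <= N")
        if not (self.alpha_post > 0 and self.beta_post > 0):
            raise ValueError("posterior shapes must be positive")

    @property
    def dist(self):
        return stats.beta(self.alpha_post, self.beta_post)


def prior_from_moments(mu: float, sigma: float) -> BetaPrior:
    """Beta shapes from a mean and standard deviation (method of moments)."""
    if not (0.0 < mu < 1.0):
        raise ValueError("mu must lie in (0, 1)")
    var = sigma * sigma
    if var <= 0 or var >= mu * (1.0 - mu):
        raise ValueError(
            f"sigma^2={var:.4g} must lie in (0, mu(1-mu)={mu * (1 - mu):.4g}) "
            "for a valid beta prior")
    alpha = mu * mu * ((1.0 - mu) / var - 1.0 / mu)
    beta = alpha * (1.0 / mu - 1.0)
    return BetaPrior(alpha=alpha, beta=beta, mu=mu, sigma=sigma)


def estimate_prior(
    profiles: Iterable[SelectivityProfile], min_screened: int = 20
) -> BetaPrior:
    """Empirical prior from hit ratios of active compounds screened against at
    least ``min_screened`` distinct targets.  Sample standard deviation
    (ddof=1) is used."""
    ratios = [p.hit_ratio for p in profiles
              if p.n_screened >= min_screened and p.target_selectivity >= 1]
    if len(ratios) < 2:
        raise ValueError("need at least 2 qualifying compounds for the prior")
    mu = float(np.mean(ratios))
    sigma = float(np.std(ratios, ddof=1))
    return prior_from_moments(mu, sigma)


def posterior(n: int, N: int, prior: BetaPrior,
              compound_id: str = "") -> HitRatioPosterior:
    """Conjugate update: Beta(alpha + n, beta + N - n)."""
    if n > N:
        raise ValueError("n cannot exceed N")
    return HitRatioPosterior(
        compound_id=compound_id, n=n, N=N,
        alpha_post=prior.alpha + n, beta_post=prior.beta + N - n)


def promiscuity_probability(
    post: HitRatioPosterior, threshold: float = DEFAULT_PROMISCUITY_THRESHOLD
) -> float:
    """Posterior tail mass P(theta >= threshold)."""
    return float(post.dist.sf(threshold))


class HitRatioModel(BaseEstimator):
    """Beta-binomial promiscuity model over selectivity profiles.

    Parameters
    ----------
    min_screened_prior : minimum screened targets for a compound to inform the
        empirical prior (active compounds only).
    min_screened_score : minimum screened targets for a compound to receive a
        promiscuity score; less-screened compounds are excluded to avoid
        overfitting on uninformative data.
    threshold : hit-ratio level defining a promiscuous binder.
    """

    def __init__(self, min_screened_prior: int = 20,
                 min_screened_score: int = 10,
                 threshold: float = DEFAULT_PROMISCUITY_THRESHOLD):
        self.min_screened_prior = min_screened_prior
        self.min_screened_score = min_screened_score
        self.threshold = threshold

    def fit(self, profiles: Sequence[SelectivityProfile], y=None):
        self.prior_ = estimate_prior(profiles, self.min_screened_prior)
        return self

    def posteriors(self, profiles: Sequence[SelectivityProfile]
                   ) -> list[HitRatioPosterior]:
        return [posterior(p.target_selectivity, p.n_screened, self.prior_,
                          compound_id=p.compound_id)
                for p in profiles if p.n_screened >= self.min_screened_score]

    def score_compounds(self, profiles: Sequence[SelectivityProfile]
                        ) -> pd.DataFrame:
        """Promiscuity scores, sorted from most promiscuous to most selective."""
        rows = []
        for post in self.posteriors(profiles):
            rows.append({
                "cid": post.compound_id, "n": post.n, "N": post.N,
                "alpha_post": post.alpha_post, "beta_post": post.beta_post,
                "prom_prob": promiscuity_probability(post, self.threshold),
            })
        frame = pd.DataFrame(
            rows, columns=["cid", "n", "N", "alpha_post", "beta_post",
                           "prom_prob"])
        return frame.sort_values(
            ["prom_prob", "cid"], ascending=[False, True], ignore_index=True)


@dataclass
class MixtureSamples:
    """Pooled equal-weight posterior samples across a compound set."""

    values: np.ndarray
    per_compound: int
    n_compounds: int

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.values, q))


def mixture_samples(
    posteriors: Sequence[HitRatioPosterior],
    per_compound: int,
    pool_size: int = 1_000_000,
    seed: int = 0,
) -> MixtureSamples:
    """Equally weighted convex combination of per-compound posteriors.

    Draws ``per_compound`` beta samples for each compound, pools them, and
    subsamples ``pool_size`` values without replacement.
    """
    if not posteriors:
        raise ValueError("need at least one posterior")
    total = per_compound * len(posteriors)
    if total < pool_size:
        raise ValueError(
            f"pool of {total} samples smaller than pool_size={pool_size}")
    rng = np.random.default_rng(seed)
    draws = np.concatenate([
        rng.beta(p.alpha_post, p.beta_post, size=per_compound)
        for p in posteriors])
    picked = rng.choice(total, size=pool_size, replace=False)
    return MixtureSamples(values=draws[picked], per_compound=per_compound,
                          n_compounds=len(posteriors))


def ks_distance(samples_a: Sequence[float], samples_b: Sequence[float]) -> float:
    """Two-sample Kolmogorov-Smirnov distance: the maximum absolute difference
    between the two empirical CDFs."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both sample sets must be non-empty")
    return float(stats.ks_2samp(a, b).statistic)


def label_sensitivity_specificity(
    prom_probs: Mapping,
    labels: Mapping,
    cutoffs: Sequence[float] = DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Cutoff sweep of an external promiscuity label against model scores.

    A compound is classified promiscuous at a cutoff when its promiscuity
    probability exceeds it (strict).  Sensitivity is the fraction of
    promiscuous-classified compounds carrying the label; specificity is the
    fraction of non-promiscuous-classified compounds without the label.
    Ratios over an empty class are reported as missing (NaN), not zero.
    """
    missing = set(prom_probs) - set(labels)
    if missing:
        raise KeyError(f"{len(missing)} scored compounds lack labels")
    cids = sorted(prom_probs, key=str)
    probs = np.array([prom_probs[c] for c in cids], dtype=float)
    flags = np.array([bool(labels[c]) for c in cids])
    rows = []
    for cut in cutoffs:
        if not (0.0 < cut < 1.0):
            raise ValueError("cutoffs must lie in (0, 1)")
        promiscuous = probs > cut
        n_prom = int(promiscuous.sum())
        n_non = int((~promiscuous).sum())
        sens = float(flags[promiscuous].mean()) if n_prom else float("nan")
        spec = float((~flags[~promiscuous]).mean()) if n_non else float("nan")
        rows.append({"cutoff": cut, "sensitivity": sens,
                     "specificity": spec, "n_promiscuous": n_prom})
    return pd.DataFrame(rows)
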