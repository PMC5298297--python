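"""Per-compound target selectivity at three grouping depths, and distribution fits.

Target selectivity counts the distinct protein sequences a compound is active
against; cluster selectivity counts sequence-similarity clusters with at least
one active member; domain selectivity counts the connected components of the
graph whose nodes are the compound's active targets and whose edges link
targets sharing a Pfam domain.  By construction
``domain <= cluster <= target <= screened`` when sequence-similar targets
share domains.

The tail of the selectivity distribution is summarised with a stretched
exponential P(x) = exp(-(x/x0)^c) fitted in log space, alongside plain
exponential and power-law comparators.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .grouping import ClusterMap, DomainMap
from .store import ACTIVE, INACTIVE, ActivityRecord, TrinaryMatrix

logger = logging.getLogger(__name__)

#: median-domain-selectivity bins: (low, high) edges, inclusive on both sides
DEFAULT_SELECTIVITY_BINS = (
    (2, 4), (5, 7.5), (8, 10.5), (11, 13.5),
    (14, 16.5), (17, 19.5), (20, 22), (23.5, 25.5),
)


@dataclass
class SelectivityProfile:
    compound_id: str
    n_screened: int
    target_selectivity: int
    cluster_selectivity: int
    domain_selectivity: int

    def __post_init__(self):
        ok = (0 <= self.domain_selectivity <= self.cluster_selectivity
              <= self.target_selectivity <= self.n_screened)
        if not ok:
            raise ValueError(
                f"selectivity nesting violated for {self.compound_id}: "
                f"{self.domain_selectivity} <= {self.cluster_selectivity} <= "
                f"{self.target_selectivity} <= {self.n_screened} expected")

    @property
    def hit_ratio(self) -> float:
        return self.target_selectivity / self.n_screened if self.n_screened else 0.0


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def domain_selectivity(active_targets: Iterable, domain_map: DomainMap) -> int:
    """Connected components of the shared-domain graph over active targets.

    Targets sharing any Pfam domain are linked; targets without domain
    annotation are isolated nodes and each contributes one component.
    """
    active_targets = set(active_targets)
    if not active_targets:
        return 0
    uf = _UnionFind(active_targets)
    by_domain: dict = {}
    for t in active_targets:
        for d in domain_map.domains(t):
            by_domain.setdefault(d, []).append(t)
    for members in by_domain.values():
        first = members[0]
        for other in members[1:]:
            uf.union(first, other)
    return len({uf.find(t) for t in active_targets})


def selectivity_profiles(
    matrix: TrinaryMatrix,
    cluster_map: ClusterMap,
    domain_map: DomainMap,
    compounds: Optional[Iterable] = None,
) -> list[SelectivityProfile]:
    """Per-compound selectivity profiles from a sequence-level trinary matrix.

    ``matrix`` columns must be sequence-level target ids (not cluster-merged),
    so that target selectivity and screening participation count distinct
    sequences.  Profiles are ordered by compound id.
    """
    compounds = sorted(matrix.rows if compounds is None else compounds, key=str)
    known = set(matrix.rows)
    screened: dict = {c: set() for c in compounds}
    actives: dict = {c: set() for c in compounds}
    wanted = set(compounds)
    for (cid, tid), code in matrix.cells.items():
        if cid not in wanted:
            continue
        screened[cid].add(tid)
        if code == ACTIVE:
            actives[cid].add(tid)
    out = []
    for cid in compounds:
        if cid not in known:
            raise KeyError(f"compound {cid!r} not present in matrix")
        act = actives[cid]
        clusters = {cluster_map.get(t, t) for t in act}
        out.append(SelectivityProfile(
            compound_id=cid,
            n_screened=len(screened[cid]),
            target_selectivity=len(act),
            cluster_selectivity=len(clusters),
            domain_selectivity=domain_selectivity(act, domain_map),
        ))
    return out


def _median(values: Sequence[float]) -> float:
    # mean of central order statistics for even sizes (half-integer bin edges)
    return statistics.median(sorted(values))


def bin_domains_by_median_selectivity(
    domain_actives: Mapping,
    profiles: Iterable[SelectivityProfile],
    min_actives: int = 10,
    bins: Sequence[tuple] = DEFAULT_SELECTIVITY_BINS,
) -> dict:
    """Assign each domain the bin holding the median domain selectivity of its
    active compounds; domains with fewer than ``min_actives`` active compounds
    are excluded.  Medians falling between bins are excluded (logged)."""
    by_cid = {p.compound_id: p for p in profiles}
    out = {}
    for domain, cids in domain_actives.items():
        scored = [by_cid[c].domain_selectivity for c in cids if c in by_cid]
        if len(scored) < min_actives:
            continue
        med = _median(scored)
        for lo, hi in bins:
            if lo <= med <= hi:
                out[domain] = (lo, hi)
                break
        else:
            logger.info("domain %s median %s falls outside all bins", domain, med)
    return out


@dataclass
class StretchedExpFit:
    """Stretched exponential fit P(x) = exp(-(x/x0)^c), with log-space R^2."""

    c: float
    x0: float
    r_squared: float

    def __post_init__(self):
        if not (self.c > 0 and self.x0 > 0):
            raise ValueError("c and x0 must be positive")

    def __call__(self, x):
        return np.exp(-((np.asarray(x, dtype=float) / self.x0) ** self.c))


@dataclass
class ComparatorFits:
    stretched: StretchedExpFit
    exponential_r_squared: float
    power_law_r_squared: float


def _log_r_squared(log_obs: np.ndarray, log_fit: np.ndarray) -> float:
    ss_res = float(np.sum((log_obs - log_fit) ** 2))
    ss_tot = float(np.sum((log_obs - log_obs.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-30 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_stretched_exponential(
    xs: Sequence[float], fractions: Sequence[float]
) -> StretchedExpFit:
    """Least-squares fit of ln P = -(x/x0)^c.

    The fit is unweighted in log space: a log-log linearisation
    (ln(-ln P) = c ln x - c ln x0) seeds a nonlinear refinement on ln P.
    Requires at least 3 points with 0 < P < 1 and x > 0.
    """
    x = np.asarray(xs, dtype=float)
    p = np.asarray(fractions, dtype=float)
    if np.any(x <= 0) or np.any(p <= 0):
        raise ValueError("xs and fractions must be positive")
    keep = p < 1.0
    x, p = x[keep], p[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 points with 0 < P < 1")
    logp = np.log(p)
    # linearisation: ln(-ln P) = c ln x - c ln x0
    slope, intercept = np.polyfit(np.log(x), np.log(-logp), 1)
    c0 = max(slope, 1e-6)
    x00 = float(np.exp(-intercept / c0))

    def model(xv, c, x0):
        return -((xv / x0) ** c)

    try:
        (c_fit, x0_fit), _ = optimize.curve_fit(
            model, x, logp, p0=(c0, x00), maxfev=20000)
    except RuntimeError:
        c_fit, x0_fit = c0, x00
    r2 = _log_r_squared(logp, model(x, c_fit, x0_fit))
    return StretchedExpFit(c=float(c_fit), x0=float(x0_fit), r_squared=r2)


def fit_with_comparators(xs, fractions) -> ComparatorFits:
    """Stretched-exponential fit plus two-parameter exponential
    (P = A exp(-x/x0)) and power-law (P = A x^-k) comparators, all scored by
    R^2 in log space."""
    x = np.asarray(xs, dtype=float)
    p = np.asarray(fractions, dtype=float)
    stretched = fit_stretched_exponential(x, p)
    keep = (p > 0) & (p < 1.0) & (x > 0)
    x, logp = x[keep], np.log(p[keep])
    # exponential: ln P = ln A - x/x0 (linear in x)
    b, a = np.polyfit(x, logp, 1)
    r2_exp = _log_r_squared(logp, a + b * x)
    # power law: ln P = ln A - k ln x (linear in ln x)
    b2, a2 = np.polyfit(np.log(x), logp, 1)
    r2_pow = _log_r_squared(logp, a2 + b2 * np.log(x))
    return ComparatorFits(stretched, r2_exp, r2_pow)


def rank_sum_one_sided(group_a: Sequence[float], group_b: Sequence[float]):
    """One-sided Mann-Whitney-Wilcoxon test that ``group_a`` is stochastically
    greater.  Returns (W, p) with W the number of pairwise wins (ties count
    1/2) and p by normal approximation with tie correction."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _participation(records: Iterable[ActivityRecord]) -> dict:
    screened: dict = {}
    for rec in records:
        screened.setdefault(rec.compound_id, set()).add(rec.target_id)
    return screened


def downsample_to_match_median(
    records: Sequence[ActivityRecord],
    group_a: Iterable,
    group_b: Iterable,
    seed: int = 0,
):
    """Equalise screening participation between two compound groups.

    Iteratively removes a random tested target (all of its records) from the
    currently most-screened ``group_a`` compound until the median number of
    screened targets in ``group_a`` is <= the ``group_b`` median.  Returns
    ``(reduced_records, removed_pairs)``; deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    group_a = sorted(set(group_a), key=str)
    group_b = set(group_b)
    screened = _participation(records)
    counts = {c: set(screened.get(c, ())) for c in group_a}
    med_b = _median([len(screened.get(c, ())) for c in group_b]) if group_b else 0

    def med_a():
        return _median([len(v) for v in counts.values()])

    removed = set()
    while counts and med_a() > med_b:
        top = max(counts, key=lambda c: (len(counts[c]), str(c)))
        targets = sorted(counts[top], key=str)
        if not targets:
            logger.warning("cannot reach target median; closest achievable "
                           "median is %s", med_a())
            break
        victim = targets[rng.integers(len(targets))]
        counts[top].discard(victim)
        removed.add((top, victim))
    reduced = [r for r in records
               if (r.compound_id, r.target_id) not in removed]
    return reduced, removed
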