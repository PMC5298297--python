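"""Sparse binary biclustering with a multiplicative Chernoff-bound score.

A bicluster is a subset of rows (compounds) and columns (target clusters)
whose submatrix is enriched for ones relative to the background density p.
With m rows, n columns and k ones, mu = m n p and delta = k / mu - 1, the
multiplicative Chernoff bound on observing at least k ones is
exp(-mu ((1+delta) ln(1+delta) - delta)); the bicluster score is that
negative exponent, normalised by m^alpha n^beta to balance growth in rows
versus columns (alpha = beta = 0.6 expresses no bias).  Higher scores mean
larger/denser submatrices that are less probable by chance.

Biclusters are found by an alternating greedy search (given columns, take the
score-maximising prefix of rows ranked by in-set ones; swap roles; iterate to
a fixed point; best over random restarts) and extracted iteratively, zeroing
each accepted bicluster before the next search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .store import ACTIVE, TrinaryMatrix

logger = logging.getLogger(__name__)


@dataclass
class Bicluster:
    rows: tuple
    cols: tuple
    k: int
    score: float

    @property
    def density(self) -> float:
        return self.k / (len(self.rows) * len(self.cols))


def chernoff_score(m: int, n: int, k: int, p: float,
                   alpha_bias: float = 0.6, beta_bias: float = 0.6) -> float:
    """Negative Chernoff-bound exponent for an m x n submatrix with k ones,
    normalised by m^alpha n^beta.  Submatrices at or below the background
    density score 0: only enrichment is rewarded."""
    if not (0.0 < p < 1.0):
        raise ValueError("background density p must lie in (0, 1)")
    if k > m * n:
        raise ValueError("k cannot exceed m*n")
    mu = m * n * p
    if k <= mu or k == 0:
        return 0.0
    # mu((1+delta)ln(1+delta) - delta) with delta = k/mu - 1
    exponent = k * np.log(k / mu) - (k - mu)
    return float(exponent / (m ** alpha_bias * n ** beta_bias))


def _prefix_scores(counts: np.ndarray, other_size: int, p: float,
                   this_bias: float, other_bias: float):
    """Best score over prefixes of indices ranked by descending counts.

    Returns (selected index array, k, score).  Scores all prefix sizes of the
    count-sorted axis in one vectorised pass; for a fixed size the best
    selection is always such a prefix because the score increases with k.
    """
    order = np.argsort(-counts, kind="stable")
    csum = np.cumsum(counts[order]).astype(float)
    sizes = np.arange(1, len(order) + 1, dtype=float)
    mu = sizes * other_size * p
    with np.errstate(divide="ignore", invalid="ignore"):
        exponent = np.where(
            (csum > mu) & (csum > 0),
            csum * np.log(np.maximum(csum, 1e-300) / mu) - (csum - mu),
            0.0,
        )
    scores = exponent / (sizes ** this_bias * other_size ** other_bias)
    best = int(np.argmax(scores))
    if scores[best] <= 0.0:
        return None
    sel = np.sort(order[: best + 1])
    return sel, int(csum[best]), float(scores[best])


def find_bicluster(
    matrix01: np.ndarray,
    background_p: Optional[float] = None,
    alpha_bias: float = 0.6,
    beta_bias: float = 0.6,
    restarts: int = 50,
    seed: int = 0,
    max_iter: int = 50,
) -> Optional[Bicluster]:
    """Single highest-scoring bicluster of a binary matrix (or None if no
    submatrix beats the background).  Alternating greedy optimisation from
    ``restarts`` random column-set initialisations; deterministic per seed."""
    X = np.asarray(matrix01)
    if X.ndim != 2 or X.size == 0:
        raise ValueError("matrix must be 2-D and non-empty")
    X = (X > 0).astype(np.int32)
    if X.sum() == 0:
        return None
    p = background_p if background_p is not None else float(X.mean())
    p = min(max(p, 1e-9), 1.0 - 1e-9)
    n_rows, n_cols = X.shape
    rng = np.random.default_rng(seed)
    # when the restart budget covers every non-empty column subset, enumerate
    # them all: combined with the optimal-prefix row/column steps this makes
    # the search exact on small matrices
    if n_cols <= 20 and 2 ** n_cols - 1 <= max(1, restarts):
        starts = [np.flatnonzero([(mask >> j) & 1 for j in range(n_cols)])
                  for mask in range(1, 2 ** n_cols)]
    else:
        starts = [None] * max(1, restarts)
    best: Optional[Bicluster] = None
    for start in starts:
        if start is None:
            cols = np.flatnonzero(rng.random(n_cols) < 0.5)
            if cols.size == 0:
                cols = np.array([rng.integers(n_cols)])
        else:
            cols = start
        rows = None
        for _ in range(max_iter):
            picked = _prefix_scores(X[:, cols].sum(axis=1), cols.size, p,
                                    alpha_bias, beta_bias)
            if picked is None:
                break
            new_rows = picked[0]
            picked = _prefix_scores(X[new_rows].sum(axis=0), new_rows.size, p,
                                    beta_bias, alpha_bias)
            if picked is None:
                break
            new_cols, k, score = picked
            if (rows is not None and np.array_equal(new_rows, rows)
                    and np.array_equal(new_cols, cols)):
                break
            rows, cols = new_rows, new_cols
        if rows is None or cols is None or len(cols) == 0:
            continue
        k = int(X[np.ix_(rows, cols)].sum())
        score = chernoff_score(len(rows), len(cols), k, p, alpha_bias, beta_bias)
        if best is None or score > best.score:
            best = Bicluster(rows=tuple(int(r) for r in rows),
                             cols=tuple(int(c) for c in cols),
                             k=k, score=score)
    return best


def iterate_biclusters(
    matrix01: np.ndarray,
    background_p: Optional[float] = None,
    alpha_bias: float = 0.6,
    beta_bias: float = 0.6,
    max_biclusters: int = 16,
    min_rows: int = 2,
    min_cols: int = 2,
    restarts: int = 50,
    seed: int = 0,
    score_floor: Optional[float] = None,
) -> list[Bicluster]:
    """Iterative extraction: find the best bicluster, zero out its cells, and
    repeat.  Clusters below ``min_rows``/``min_cols`` are discarded but still
    zeroed; extraction stops at ``max_biclusters`` accepted clusters or when
    the best score falls below ``score_floor`` (default: the score of the
    smallest admissible all-ones block, ``min_rows`` x ``min_cols``)."""
    X = (np.asarray(matrix01) > 0).astype(np.int32).copy()
    if X.size == 0:
        return []
    p = background_p if background_p is not None else float(X.mean())
    if not (0.0 < p < 1.0):
        return []
    if score_floor is None:
        score_floor = chernoff_score(min_rows, min_cols, min_rows * min_cols,
                                     p, alpha_bias, beta_bias)
    rng = np.random.default_rng(seed)
    accepted: list[Bicluster] = []
    max_extractions = max_biclusters * 10 + 10
    for _ in range(max_extractions):
        if len(accepted) >= max_biclusters:
            break
        bc = find_bicluster(X, background_p=p, alpha_bias=alpha_bias,
                            beta_bias=beta_bias, restarts=restarts,
                            seed=int(rng.integers(2 ** 31)))
        if bc is None or bc.score < score_floor:
            break
        X[np.ix_(bc.rows, bc.cols)] = 0
        if len(bc.rows) >= min_rows and len(bc.cols) >= min_cols:
            accepted.append(bc)
        else:
            logger.debug("discarded undersized bicluster %dx%d (still zeroed)",
                         len(bc.rows), len(bc.cols))
    return accepted


class BicBin(BaseEstimator):
    """Chernoff-bound biclustering estimator over a binary matrix.

    After :meth:`fit`, ``biclusters_`` holds the accepted clusters in
    extraction (decreasing-score) order and ``background_p_`` the density
    used.  ``alpha_bias``/``beta_bias`` control the row/column normalisation
    exponents (0.6/0.6 = unbiased).
    """

    def __init__(self, alpha_bias: float = 0.6, beta_bias: float = 0.6,
                 background_p: Optional[float] = None, max_biclusters: int = 16,
                 min_rows: int = 2, min_cols: int = 2, restarts: int = 50,
                 random_state: int = 0):
        self.alpha_bias = alpha_bias
        self.beta_bias = beta_bias
        self.background_p = background_p
        self.max_biclusters = max_biclusters
        self.min_rows = min_rows
        self.min_cols = min_cols
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        X = (np.asarray(X) > 0).astype(np.int32)
        self.background_p_ = (self.background_p if self.background_p is not None
                              else float(X.mean()))
        self.biclusters_ = iterate_biclusters(
            X, background_p=self.background_p_, alpha_bias=self.alpha_bias,
            beta_bias=self.beta_bias, max_biclusters=self.max_biclusters,
            min_rows=self.min_rows, min_cols=self.min_cols,
            restarts=self.restarts, seed=self.random_state)
        return self


def build_binary_drug_target_matrix(
    matrix: TrinaryMatrix, annotation_pairs: Iterable[tuple]
) -> tuple[np.ndarray, list, list]:
    """Binary drug-target matrix: 1 iff active in the assay matrix OR
    annotated as a known drug-target pair; untested and inactive cells are 0.
    Returns ``(matrix01, row_ids, col_ids)``."""
    X = (matrix.to_dense() == ACTIVE).astype(np.int8)
    row_index = {r: i for i, r in enumerate(matrix.rows)}
    col_index = {c: i for i, c in enumerate(matrix.cols)}
    for cid, tid in annotation_pairs:
        if cid not in row_index or tid not in col_index:
            raise KeyError(f"annotation pair ({cid!r}, {tid!r}) not in matrix")
        X[row_index[cid], col_index[tid]] = 1
    return X, list(matrix.rows), list(matrix.cols)
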