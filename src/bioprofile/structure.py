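"""Compound-structure clustering vs bioactivity biclustering comparison.

Compounds are clustered by structural similarity (Tanimoto over binary
fingerprints, e.g. atom-pair descriptors computed externally) with classical
multidimensional scaling for visualisation and complete-linkage hierarchical
clustering cut at k groups.  Agreement between the structural clustering and
the bioactivity bicluster assignment is the Jaccard index over co-clustered
compound pairs, referenced against a null of random size-weighted groupings.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

UNCLUSTERED = -1  # label for compounds outside every bicluster


def tanimoto_distance_matrix(fps: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Tanimoto distances between binary fingerprint rows.

    The Tanimoto coefficient of two bit vectors is |a AND b| / |a OR b|.
    Pairs involving an all-zero fingerprint have an undefined coefficient and
    are assigned distance 1 (with a warning); the diagonal is 0.
    """
    F = (np.asarray(fps) > 0).astype(np.int64)
    if F.ndim != 2 or F.shape[0] < 2:
        raise ValueError("need at least 2 fingerprint rows")
    inter = F @ F.T
    sizes = F.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    if np.any(sizes == 0):
        warnings.warn("all-zero fingerprints present; their pairwise "
                      "distances are defined as 1", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tanimoto = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    dist = 1.0 - tanimoto
    np.fill_diagonal(dist, 0.0)
    return dist


def classical_mds(distances: np.ndarray, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS: double centering of squared distances and
    embedding on the top eigenvectors.  Exactly reproduces configurations for
    Euclidean-realisable inputs up to rigid motion; negative eigenvalues
    (non-Euclidean residuals) are truncated at zero."""
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:dims]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)[None, :]


def complete_linkage_cut(distances: np.ndarray, k: int = 11) -> np.ndarray:
    """Complete-linkage hierarchical clustering cut into exactly ``k`` groups.

    Returns integer labels (0-based).  ``k`` must not exceed the number of
    observations.
    """
    D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds {n} observations")
    if k == n:
        return np.arange(n)
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return labels - 1


def _copair_counts(labels_a: np.ndarray, labels_b: np.ndarray):
    """(pairs co-clustered in both, in a, in b) via the contingency table.

    Negative labels mark unclustered compounds: each is treated as its own
    singleton and so contributes no pairs.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    both = 0
    from collections import Counter
    joint = Counter((x, y) for x, y in zip(a, b) if x >= 0 and y >= 0)
    both = sum(comb(c, 2) for c in joint.values())
    in_a = sum(comb(c, 2) for c in Counter(x for x in a if x >= 0).values())
    in_b = sum(comb(c, 2) for c in Counter(y for y in b if y >= 0).values())
    return both, in_a, in_b


def jaccard_between_clusterings(
    labels_a: Sequence[int], labels_b: Sequence[int]
) -> Optional[float]:
    """Jaccard index over co-clustered pairs: |pairs joined by both| /
    |pairs joined by either|.  Returns None when neither clustering joins any
    pair (all singletons).  Compounds labelled ``UNCLUSTERED`` (negative) are
    excluded from pair counting."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("clusterings must cover the same compound universe")
    both, in_a, in_b = _copair_counts(a, b)
    union = in_a + in_b - both
    if union == 0:
        return None
    return both / union


def bicluster_labels(biclusters, row_ids: Sequence) -> np.ndarray:
    """Compound labels from bicluster memberships: each compound is assigned
    its lowest-numbered bicluster; compounds in none get ``UNCLUSTERED``."""
    labels = np.full(len(row_ids), UNCLUSTERED, dtype=int)
    index = {r: i for i, r in enumerate(row_ids)}
    for b_idx, bc in enumerate(biclusters):
        for r in bc.rows:
            pos = index[r] if r in index else r  # ids or positional rows
            if labels[pos] == UNCLUSTERED:
                labels[pos] = b_idx
    return labels


@dataclass
class ClusteringComparison:
    jaccard_observed: float
    null_mean: float
    null_sd: float
    permutation_p: float
    n_permutations: int


def permutation_null(
    labels_structure: Sequence[int],
    labels_bioactivity: Sequence[int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> ClusteringComparison:
    """Size-weighted random-clustering null for the Jaccard agreement.

    Each permutation replaces the structural clustering with an independent
    random assignment of compounds to clusters, with probabilities
    proportional to the structural cluster sizes, and recomputes the Jaccard
    index against the bioactivity clustering.  The permutation p-value uses
    the add-one correction (1 + #{J_null >= J_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    s = np.asarray(labels_structure)
    bio = np.asarray(labels_bioactivity)
    obs = jaccard_between_clusterings(s, bio)
    if obs is None:
        raise ValueError("observed Jaccard undefined (all singletons)")
    clustered = s[s >= 0]
    uniq, counts = np.unique(clustered, return_counts=True)
    weights = counts / counts.sum()
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for i in range(n_perm):
        rand = s.copy()
        rand[s >= 0] = rng.choice(uniq, size=clustered.size, p=weights)
        j = jaccard_between_clusterings(rand, bio)
        nulls[i] = 0.0 if j is None else j
    n_ge = int(np.sum(nulls >= obs))
    return ClusteringComparison(
        jaccard_observed=float(obs),
        null_mean=float(nulls.mean()),
        null_sd=float(nulls.std(ddof=1)) if n_perm > 1 else 0.0,
        permutation_p=(1 + n_ge) / (1 + n_perm),
        n_permutations=n_perm,
    )
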