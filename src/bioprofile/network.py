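"""Target-protein network from trinary bioactivity-profile similarity.

Two target columns are compared over their mutually tested compounds with a
Tanimoto (intersection over union) of active-compound sets.  Pairs with fewer
than 12 mutually screened compounds or fewer than 3 actives carry
insufficient evidence and score 0.  Edges connect target pairs with
similarity >= 0.50; highly promiscuous compounds (posterior promiscuity
probability above 0.5) are excluded beforehand so that spurious edges from
unselective binders do not dominate the graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .store import ACTIVE, UNTESTED, TrinaryMatrix

DEFAULT_MIN_COMMON = 12
DEFAULT_MIN_ACTIVES = 3
DEFAULT_EDGE_THRESHOLD = 0.50


def trinary_similarity(
    col_a: Sequence[int],
    col_b: Sequence[int],
    min_common: int = DEFAULT_MIN_COMMON,
    min_actives: int = DEFAULT_MIN_ACTIVES,
    min_actives_scope: str = "union",
) -> float:
    """Tanimoto similarity of two trinary profile columns over mutually
    tested compounds, with evidence gates.

    Columns are code vectors (0=untested, 1=inactive, 2=active) over the same
    compound universe.  Pairs with fewer than ``min_common`` mutually tested
    compounds, or fewer than ``min_actives`` actives (in the union of the two
    active sets by default, or on each side with scope="each"), score 0.
    """
    a = np.asarray(col_a)
    b = np.asarray(col_b)
    if a.shape != b.shape:
        raise ValueError("columns must cover the same compound universe")
    mutual = (a != UNTESTED) & (b != UNTESTED)
    if int(mutual.sum()) < min_common:
        return 0.0
    act_a = (a == ACTIVE) & mutual
    act_b = (b == ACTIVE) & mutual
    inter = int((act_a & act_b).sum())
    union = int((act_a | act_b).sum())
    if min_actives_scope == "union":
        if union < min_actives:
            return 0.0
    elif min_actives_scope == "each":
        if int(act_a.sum()) < min_actives or int(act_b.sum()) < min_actives:
            return 0.0
    else:
        raise ValueError("min_actives_scope must be 'union' or 'each'")
    return inter / union


def exclude_promiscuous(
    compounds: Iterable, prom_probs: Mapping, cutoff: float = 0.5
) -> set:
    """Drop compounds whose promiscuity probability strictly exceeds the
    cutoff; unscored (infrequently screened) compounds are retained."""
    return {c for c in compounds
            if not (c in prom_probs and prom_probs[c] > cutoff)}


@dataclass
class TPGraphStats:
    n_nodes: int
    n_edges: int
    n_components: int
    mean_degree: float
    density: float


def build_tp_graph(
    matrix: TrinaryMatrix,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
    min_common: int = DEFAULT_MIN_COMMON,
    min_actives: int = DEFAULT_MIN_ACTIVES,
    min_actives_scope: str = "union",
    retain_compounds: Optional[Iterable] = None,
    node_attrs: Optional[Mapping] = None,
) -> tuple[nx.Graph, TPGraphStats]:
    """Bioactivity-similarity network over the matrix's target columns.

    Targets are connected when their trinary similarity is >= ``threshold``
    (with the evidence gates of :func:`trinary_similarity`); isolated targets
    are excluded from the node set.  ``retain_compounds`` restricts the
    compound universe (e.g. after excluding promiscuous binders).  Similarity
    is computed for all column pairs with vectorised set algebra.
    """
    if len(matrix.cols) < 2:
        raise ValueError("need at least 2 target columns")
    dense = matrix.to_dense()
    if retain_compounds is not None:
        keep = set(retain_compounds)
        rows_keep = [i for i, r in enumerate(matrix.rows) if r in keep]
        dense = dense[rows_keep]
    T = (dense != UNTESTED).astype(np.int64)
    A = (dense == ACTIVE).astype(np.int64)
    mutual = T.T @ T                   # mutually tested counts
    inter = A.T @ A                    # co-active among mutual
    a_on_mutual = A.T @ T              # actives of i among pairs tested in j
    union = a_on_mutual + a_on_mutual.T - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    gate = mutual >= min_common
    if min_actives_scope == "union":
        gate &= union >= min_actives
    elif min_actives_scope == "each":
        gate &= (a_on_mutual >= min_actives) & (a_on_mutual.T >= min_actives)
    else:
        raise ValueError("min_actives_scope must be 'union' or 'each'")
    sim = np.where(gate, sim, 0.0)
    np.fill_diagonal(sim, 0.0)

    graph = nx.Graph()
    cols = list(matrix.cols)
    ii, jj = np.nonzero(np.triu(sim >= threshold, k=1))
    for i, j in zip(ii, jj):
        graph.add_edge(cols[i], cols[j], similarity=float(sim[i, j]))
    if node_attrs:
        for node in graph.nodes:
            for key, val in node_attrs.get(node, {}).items():
                graph.nodes[node][key] = val
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    stats = TPGraphStats(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_components=nx.number_connected_components(graph),
        mean_degree=(2.0 * n_edges / n_nodes) if n_nodes else 0.0,
        density=(2.0 * n_edges / (n_nodes * (n_nodes - 1)))
        if n_nodes > 1 else 0.0,
    )
    return graph, stats


def write_gml(graph: nx.Graph, path) -> None:
    """Write the network as GML text (Gephi readable)."""
    nx.write_gml(graph, path, stringizer=str)
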