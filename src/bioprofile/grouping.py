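"""Target grouping schemes: sequence clusters, domain maps, clique de-duplication.

Protein targets are grouped at three evolutionary depths: (i) identical
sequences (the raw target ids), (ii) sequence-similarity clusters
(single-linkage components over a pairwise identity/coverage table), and
(iii) Pfam-domain based groupings, either fuzzy single-domain clusters or
strict domain-composition clusters (identical domain sets).  Single-domain
clusters of co-occurring domains are de-duplicated by iteratively extracting
the largest clique of the domain co-occurrence graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

MAX_EXACT_CLIQUE_NODES = 2000


@dataclass
class ClusterMap:
    """Partition of targets into sequence clusters, with optional representatives."""

    target_to_cluster: dict
    representatives: dict = field(default_factory=dict)

    def __post_init__(self):
        members = {}
        for t, c in self.target_to_cluster.items():
            members.setdefault(c, set()).add(t)
        self.cluster_members = members
        for c, rep in self.representatives.items():
            if rep not in members.get(c, ()):
                raise ValueError(f"representative {rep!r} is not a member of {c!r}")

    def __getitem__(self, target_id):
        return self.target_to_cluster[target_id]

    def __contains__(self, target_id):
        return target_id in self.target_to_cluster

    def get(self, target_id, default=None):
        return self.target_to_cluster.get(target_id, default)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_members)


@dataclass
class DomainMap:
    """Target -> Pfam-like domain set mapping (fuzzy single-domain clustering)."""

    target_to_domains: dict

    def __post_init__(self):
        self.target_to_domains = {
            t: frozenset(d) for t, d in self.target_to_domains.items()
        }
        inv: dict = {}
        for t, doms in self.target_to_domains.items():
            for d in doms:
                inv.setdefault(d, set()).add(t)
        self.domain_to_targets = inv

    def domains(self, target_id) -> frozenset:
        return self.target_to_domains.get(target_id, frozenset())


def greedy_sequence_clusters(
    pairwise: Iterable[tuple],
    id_min: float = 0.60,
    cov_min: float = 0.80,
    targets: Optional[Iterable] = None,
) -> ClusterMap:
    """Single-linkage sequence clusters from a pairwise (a, b, identity, coverage) table.

    A pair links its two targets when identity >= ``id_min`` and coverage >=
    ``cov_min``; clusters are the connected components of the resulting graph.
    Targets appearing only in failing pairs (or listed in ``targets``) become
    singletons.  Cluster ids are ``CL``-prefixed, numbered by the
    lexicographically smallest member.
    """
    graph = nx.Graph()
    if targets is not None:
        graph.add_nodes_from(targets)
    for i, row in enumerate(pairwise):
        try:
            a, b, ident, cov = row
            ident = float(ident)
            cov = float(cov)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed pairwise row {i}: {row!r}") from exc
        if not (0.0 <= ident <= 1.0 and 0.0 <= cov <= 1.0):
            raise ValueError(f"identity/coverage out of [0,1] at row {i}: {row!r}")
        graph.add_node(a)
        graph.add_node(b)
        if ident >= id_min and cov >= cov_min:
            graph.add_edge(a, b)
    components = sorted(
        (sorted(comp, key=str) for comp in nx.connected_components(graph)),
        key=lambda comp: str(comp[0]),
    )
    mapping = {}
    for idx, comp in enumerate(components):
        cid = f"CL{idx:05d}"
        for t in comp:
            mapping[t] = cid
    return ClusterMap(mapping)


#: precedence classes for representative selection, best first
_REP_PRECEDENCE = (
    lambda a: a.get("is_annotated_drug_target", False) and a.get("is_human", False),
    lambda a: a.get("is_human", False) and a.get("has_uniprot", False),
    lambda a: a.get("has_uniprot", False),
    lambda a: True,
)


def choose_representative(members: Iterable, annotations: Mapping) -> str:
    """Highest-precedence cluster member: annotated human drug target, then
    human with a UniProt id, then any target with a UniProt id, then the rest.
    Ties break lexicographically by id."""
    members = sorted(members, key=str)
    if not members:
        raise ValueError("empty cluster")

    def rank(t):
        ann = annotations.get(t, {})
        for level, pred in enumerate(_REP_PRECEDENCE):
            if pred(ann):
                return level
        return len(_REP_PRECEDENCE)

    return min(members, key=lambda t: (rank(t), str(t)))


def composition_clusters(
    domain_map: DomainMap, include_single_domain: bool = False
) -> dict:
    """Group targets by set-equality of their domain sets (order is irrelevant).

    By default only multi-domain targets are clustered; single-domain targets
    are trivially their own single-domain cluster.
    """
    out: dict = {}
    for t, doms in domain_map.target_to_domains.items():
        if not doms:
            continue
        if len(doms) < 2 and not include_single_domain:
            continue
        out.setdefault(doms, set()).add(t)
    return out


def _greedy_clique(graph: nx.Graph) -> list:
    """Greedy max-clique heuristic used beyond the exact-search size guard."""
    best: list = []
    for seed in sorted(graph.nodes, key=lambda n: (-graph.degree(n), str(n))):
        clique = [seed]
        candidates = set(graph[seed])
        while candidates:
            nxt = min(candidates,
                      key=lambda n: (-len(candidates & set(graph[n])), str(n)))
            clique.append(nxt)
            candidates &= set(graph[nxt])
        if len(clique) > len(best):
            best = clique
    return best


def dedupe_domains(
    domains: Iterable,
    cooccurrence_edges: Iterable[tuple],
    screened_counts: Mapping,
) -> list[tuple]:
    """Iteratively extract the largest clique of the domain co-occurrence graph.

    Each extracted clique is removed before the next iteration, so every
    domain lands in exactly one clique and clique sizes are non-increasing.
    Clique ties break by (greater total screened count, lexicographically
    smallest member set); the representative is the clique member occurring in
    the most screened targets (ties lexicographic).

    Returns a list of ``(clique_members, representative)`` in extraction order.
    """
    graph = nx.Graph()
    graph.add_nodes_from(domains)
    for a, b in cooccurrence_edges:
        if a not in graph or b not in graph:
            raise ValueError(f"edge ({a!r}, {b!r}) references unlisted domain")
        if a != b:
            graph.add_edge(a, b)

    result = []
    while graph.number_of_nodes():
        if graph.number_of_nodes() <= MAX_EXACT_CLIQUE_NODES:
            cliques = [sorted(c, key=str) for c in nx.find_cliques(graph)]

            def size_key(c):
                return (len(c), sum(screened_counts.get(d, 0) for d in c))

            best = max(size_key(c) for c in cliques)
            # among size/screened-count ties, lexicographically smallest members
            clique = min((c for c in cliques if size_key(c) == best),
                         key=lambda c: tuple(str(d) for d in c))
        else:
            logger.warning("graph exceeds %d nodes; greedy clique heuristic used",
                           MAX_EXACT_CLIQUE_NODES)
            clique = sorted(_greedy_clique(graph), key=str)
        rep = max(clique, key=lambda d: (screened_counts.get(d, 0), str(d)))
        result.append((list(clique), rep))
        graph.remove_nodes_from(clique)
    return result
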