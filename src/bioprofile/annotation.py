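"""Assay-activity vs external annotation comparison, and term enrichment.

Every compound-target pair of the screening matrix falls in exactly one of
six cells: {untested, inactive, active} x {unannotated, annotated}.  Actives
without annotation are the candidate novel drug-target pairs.  Term
over-representation (GO slim, Pfam, ...) in a member set against a background
set is scored with the upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from scipy import stats

from .store import ACTIVE, INACTIVE, UNTESTED, TrinaryMatrix

STATES = ("untested", "inactive", "active")
_STATE_NAME = {UNTESTED: "untested", INACTIVE: "inactive", ACTIVE: "active"}


@dataclass
class ComparisonTable:
    """Six-cell partition of compound-target pairs by activity and annotation."""

    counts: dict  # (state, "annotated"|"unannotated") -> count
    novel_actives: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_agree(self) -> int:
        return self.counts[("active", "annotated")]

    @property
    def n_disagree(self) -> int:
        return self.counts[("inactive", "annotated")]


def compare_matrix_to_annotations(
    matrix: TrinaryMatrix, annotated_pairs: Iterable[tuple]
) -> ComparisonTable:
    """Classify every matrix pair into the six activity x annotation cells.

    ``annotated_pairs`` are (compound_id, column_id) tuples referencing matrix
    ids.  The "novel active" list (active but unannotated pairs) is returned
    alongside the counts.
    """
    rows, cols = set(matrix.rows), set(matrix.cols)
    annotated = set()
    for cid, tid in annotated_pairs:
        if cid not in rows or tid not in cols:
            raise KeyError(f"annotated pair ({cid!r}, {tid!r}) not in matrix")
        annotated.add((cid, tid))
    counts = {(s, a): 0 for s in STATES for a in ("unannotated", "annotated")}
    # tested cells
    for key, code in matrix.cells.items():
        ann = "annotated" if key in annotated else "unannotated"
        counts[(_STATE_NAME[code], ann)] += 1
    # untested cells by complement
    n_annotated_untested = sum(
        1 for key in annotated if key not in matrix.cells)
    total = len(matrix.rows) * len(matrix.cols)
    counts[("untested", "annotated")] = n_annotated_untested
    counts[("untested", "unannotated")] = (
        total - len(matrix.cells) - n_annotated_untested)
    novel = sorted(
        (key for key, code in matrix.cells.items()
         if code == ACTIVE and key not in annotated),
        key=lambda k: (str(k[0]), str(k[1])))
    return ComparisonTable(counts=counts, novel_actives=novel)


@dataclass
class EnrichmentResult:
    term: str
    members_with_term: int
    members: int
    background_with_term: int
    background: int
    p_value: float


def hypergeometric_enrichment(
    member_terms: Mapping,
    background_terms: Mapping,
    min_members_with_term: int = 1,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric enrichment of terms in a member set.

    ``member_terms`` / ``background_terms`` map entity id -> set of term ids;
    members must be a subset of the background.  For each term, the p-value is
    P(X >= members_with_term) drawing ``|members|`` entities from a population
    of ``|background|`` containing ``background_with_term`` successes.
    Results are sorted by increasing p-value.  No multiple-testing correction
    is applied (terms are typically displayed at a raw p <= 0.05).
    """
    extra = set(member_terms) - set(background_terms)
    if extra:
        raise ValueError(f"{len(extra)} members missing from background")
    n_bg = len(background_terms)
    n_mem = len(member_terms)
    term_bg: dict = {}
    for terms in background_terms.values():
        for t in terms:
            term_bg[t] = term_bg.get(t, 0) + 1
    term_mem: dict = {}
    for terms in member_terms.values():
        for t in terms:
            term_mem[t] = term_mem.get(t, 0) + 1
    results = []
    for term, k in term_mem.items():
        if k < min_members_with_term:
            continue
        K = term_bg[term]
        p = float(stats.hypergeom.sf(k - 1, n_bg, K, n_mem))
        results.append(EnrichmentResult(
            term=term, members_with_term=k, members=n_mem,
            background_with_term=K, background=n_bg,
            p_value=min(p, 1.0)))
    results.sort(key=lambda r: (r.p_value, str(r.term)))
    return results
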