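"""Activity records and the sparse trinary compound x target matrix.

High-throughput screening outcomes arrive as per-assay records (assay,
compound, target, active/inactive).  Repeated measurements of the same
compound-target pair across assays are merged into a single trinary cell
(untested / inactive / active) with active outcomes taking precedence over
inactive ones, optionally after collapsing sequence-similar targets into a
common column.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional

import numpy as np

logger = logging.getLogger(__name__)

# trinary cell codes (serialized form)
UNTESTED = 0
INACTIVE = 1
ACTIVE = 2

OUTCOMES = ("active", "inactive")


class ActivityRecord(NamedTuple):
    """One binary screening outcome for a compound against a protein target."""

    assay_id: str
    compound_id: str
    target_id: str
    outcome: str  # "active" | "inactive"
    score: Optional[float] = None


@dataclass
class TrinaryMatrix:
    """Sparse compound x target-column matrix with cells in {untested, inactive, active}.

    Unstored cells are untested; ``cells`` maps ``(compound_id, column_id)``
    to :data:`INACTIVE` or :data:`ACTIVE`.
    """

    rows: list
    cols: list
    cells: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.rows)) != len(self.rows):
            raise ValueError("duplicate row ids")
        if len(set(self.cols)) != len(self.cols):
            raise ValueError("duplicate column ids")
        self._row_index = {r: i for i, r in enumerate(self.rows)}
        self._col_index = {c: i for i, c in enumerate(self.cols)}

    @property
    def shape(self) -> tuple:
        return (len(self.rows), len(self.cols))

    def get(self, compound_id, column_id) -> int:
        return self.cells.get((compound_id, column_id), UNTESTED)

    def to_dense(self) -> np.ndarray:
        """Dense int8 array with codes 0=untested, 1=inactive, 2=active."""
        dense = np.zeros(self.shape, dtype=np.int8)
        for (r, c), code in self.cells.items():
            dense[self._row_index[r], self._col_index[c]] = code
        return dense

    def row(self, compound_id) -> dict:
        return {c: v for (r, c), v in self.cells.items() if r == compound_id}

    def active_columns(self, compound_id) -> set:
        return {c for (r, c), v in self.cells.items()
                if r == compound_id and v == ACTIVE}


def build_matrix(
    records: Iterable[ActivityRecord],
    cluster_map: Optional[Mapping] = None,
    strict: bool = False,
) -> TrinaryMatrix:
    """Assemble the trinary matrix, merging targets in the same sequence cluster.

    Cells merge all records for a (compound, cluster) key; an active outcome
    anywhere takes precedence over inactive ones.  Targets missing from
    ``cluster_map`` fall back to singleton clusters named by the target id
    (with a warning), or raise when ``strict``.  Records with outcomes other
    than active/inactive (e.g. inconclusive) are dropped with a logged count.
    """
    cluster_map = cluster_map or {}
    cells: dict = {}
    rows: dict = {}
    cols: dict = {}
    n_unmapped = 0
    n_dropped = 0
    for rec in records:
        if rec.outcome not in OUTCOMES:
            n_dropped += 1
            continue
        if rec.target_id in cluster_map:
            col = cluster_map[rec.target_id]
        else:
            if strict:
                raise KeyError(f"target {rec.target_id!r} missing from cluster map")
            n_unmapped += 1
            col = rec.target_id
        rows.setdefault(rec.compound_id, None)
        cols.setdefault(col, None)
        key = (rec.compound_id, col)
        code = ACTIVE if rec.outcome == "active" else INACTIVE
        cells[key] = max(cells.get(key, UNTESTED), code)
    if n_unmapped and cluster_map:
        logger.warning("%d records had targets absent from the cluster map; "
                       "used singleton clusters", n_unmapped)
    if n_dropped:
        logger.info("dropped %d records with non-binary outcomes", n_dropped)
    return TrinaryMatrix(rows=sorted(rows), cols=sorted(cols, key=str), cells=cells)


def highly_screened(
    records: Iterable[ActivityRecord],
    min_targets: int = 10,
    require_active: bool = False,
) -> set:
    """Compounds screened against at least ``min_targets`` distinct sequence-level
    targets (and, optionally, active against at least one)."""
    if min_targets < 1:
        raise ValueError("min_targets must be >= 1")
    screened = defaultdict(set)
    actives = set()
    for rec in records:
        if rec.outcome not in OUTCOMES:
            continue
        screened[rec.compound_id].add(rec.target_id)
        if rec.outcome == "active":
            actives.add(rec.compound_id)
    out = {c for c, t in screened.items() if len(t) >= min_targets}
    if require_active:
        out &= actives
    return out


@dataclass
class ReplicatePairCounts:
    """Agreement tallies over compound-target pairs measured in exactly two assays."""

    n_agree_active: float
    n_agree_inactive: float
    n_disagree: float

    @property
    def total(self) -> float:
        return self.n_agree_active + self.n_agree_inactive + self.n_disagree


def replication_counts(
    records: Iterable[ActivityRecord],
) -> tuple[Counter, ReplicatePairCounts]:
    """Partition compound-target pairs by how many distinct assays measured them.

    Returns ``(times_screened -> n_pairs, agreement counts for exactly-twice
    pairs)``.  The three exactly-twice counts sum to the number of pairs
    measured twice.
    """
    outcomes = defaultdict(list)
    for rec in records:
        if rec.outcome not in OUTCOMES:
            continue
        outcomes[(rec.compound_id, rec.target_id)].append(rec.outcome)
    times = Counter(len(v) for v in outcomes.values())
    aa = ai = dd = 0
    for v in outcomes.values():
        if len(v) != 2:
            continue
        if v[0] != v[1]:
            dd += 1
        elif v[0] == "active":
            aa += 1
        else:
            ai += 1
    return times, ReplicatePairCounts(aa, ai, dd)


def density_summary(matrix: TrinaryMatrix) -> dict:
    """Tested and active densities of the matrix.

    ``active_fraction_of_total == tested_fraction * active_fraction_of_tested``
    by construction.
    """
    n_rows, n_cols = matrix.shape
    total = n_rows * n_cols
    if total == 0:
        raise ValueError("empty matrix")
    n_tested = len(matrix.cells)
    n_active = sum(1 for v in matrix.cells.values() if v == ACTIVE)
    tested_fraction = n_tested / total
    active_of_tested = n_active / n_tested if n_tested else 0.0
    return {
        "tested_fraction": tested_fraction,
        "active_fraction_of_tested": active_of_tested,
        "active_fraction_of_total": n_active / total,
    }
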