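"""Plain-text TSV readers and writers for the pipeline's exchange formats."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .store import ACTIVE, INACTIVE, ActivityRecord, TrinaryMatrix


def read_activity_tsv(path) -> list[ActivityRecord]:
    """Activity records TSV: assay_id, cid, target_id, outcome[, score]."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"assay_id", "cid", "target_id", "outcome"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"activity TSV missing columns: {sorted(missing)}")
    has_score = "score" in frame.columns
    records = []
    for row in frame.itertuples(index=False):
        score = None
        if has_score and not pd.isna(row.score):
            score = float(row.score)
        records.append(ActivityRecord(
            assay_id=row.assay_id, compound_id=row.cid,
            target_id=row.target_id, outcome=row.outcome, score=score))
    return records


def write_activity_tsv(records: Iterable[ActivityRecord], path) -> None:
    frame = pd.DataFrame(
        [(r.assay_id, r.compound_id, r.target_id, r.outcome, r.score)
         for r in records],
        columns=["assay_id", "cid", "target_id", "outcome", "score"])
    frame.to_csv(path, sep="\t", index=False)


def read_map_tsv(path, key_col=0, value_col=1) -> dict:
    """Two-column mapping TSV (e.g. target_id -> cluster_id), header included."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(frame.iloc[:, key_col], frame.iloc[:, value_col]))


def write_map_tsv(mapping: Mapping, path, columns: Sequence[str]) -> None:
    frame = pd.DataFrame(sorted(mapping.items()), columns=list(columns))
    frame.to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[tuple]:
    """Two-column pair TSV (e.g. cid, target_id), header included."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [tuple(row) for row in frame.itertuples(index=False)]


def write_pairs_tsv(pairs: Iterable[tuple], path, columns: Sequence[str]) -> None:
    frame = pd.DataFrame(list(pairs), columns=list(columns))
    frame.to_csv(path, sep="\t", index=False)


def read_domain_map(path) -> dict:
    """Domain TSV (target_id, domain_id) -> target_id -> set of domains."""
    out: dict = {}
    for tid, dom in read_pairs_tsv(path):
        out.setdefault(tid, set()).add(dom)
    return {t: frozenset(d) for t, d in out.items()}


def read_id_list(path) -> set:
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_id_list(ids: Iterable, path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


def write_matrix_tsv(matrix: TrinaryMatrix, path) -> None:
    """Sparse triplet TSV (cid, cluster_id, code) with 1=inactive, 2=active."""
    rows = sorted(((r, c, v) for (r, c), v in matrix.cells.items()),
                  key=lambda t: (str(t[0]), str(t[1])))
    frame = pd.DataFrame(rows, columns=["cid", "cluster_id", "code"])
    frame.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> TrinaryMatrix:
    frame = pd.read_csv(path, sep="\t",
                        dtype={"cid": str, "cluster_id": str, "code": int})
    cells = {}
    for row in frame.itertuples(index=False):
        if row.code not in (INACTIVE, ACTIVE):
            raise ValueError(f"invalid trinary code {row.code}")
        cells[(row.cid, row.cluster_id)] = int(row.code)
    rows = sorted({k[0] for k in cells})
    cols = sorted({k[1] for k in cells})
    return TrinaryMatrix(rows=rows, cols=cols, cells=cells)


def write_profiles_tsv(profiles, path) -> None:
    frame = pd.DataFrame(
        [(p.compound_id, p.n_screened, p.target_selectivity,
          p.cluster_selectivity, p.domain_selectivity) for p in profiles],
        columns=["cid", "n_screened", "target_sel", "cluster_sel", "domain_sel"])
    frame.to_csv(path, sep="\t", index=False)


def read_profiles_tsv(path):
    from .selectivity import SelectivityProfile
    frame = pd.read_csv(path, sep="\t", dtype={"cid": str})
    return [SelectivityProfile(
        compound_id=row.cid, n_screened=int(row.n_screened),
        target_selectivity=int(row.target_sel),
        cluster_selectivity=int(row.cluster_sel),
        domain_selectivity=int(row.domain_sel))
        for row in frame.itertuples(index=False)]


def write_fingerprints(fingerprints: pd.DataFrame, path) -> None:
    """Fingerprint TSV: cid and the bitstring of each compound."""
    bits = ["".join(map(str, row)) for row in
            fingerprints.to_numpy(dtype=int)]
    pd.DataFrame({"cid": fingerprints.index, "bits": bits}).to_csv(
        path, sep="\t", index=False)


def read_fingerprints(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    mat = np.array([[int(ch) for ch in b] for b in frame["bits"]], dtype=np.int8)
    return pd.DataFrame(mat, index=pd.Index(frame["cid"], name="cid"))
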