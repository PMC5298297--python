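"""Seeded synthetic bioactivity worlds with known ground truth.

The generator emulates the statistical structure of large public screening
corpora: a sparse trinary compound x target matrix (a few percent of pairs
tested, of which on the order of one percent are active), compounds with
heterogeneous screening participation, a symmetric per-measurement flip error
applied independently to every outcome, replicated measurements of a fraction
of tested pairs, compound classes differing in hit ratio (selective,
family-cross-reactive, promiscuous, inactive), multi-domain targets grouped
into sequence families whose members share a family-core domain, and
optionally planted dense activity biclusters.

Every quantity downstream stages estimate (flip error rate, per-class hit
ratios, family structure, bicluster memberships) is recorded as ground truth,
so parameter recovery can be checked exactly.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .store import ActivityRecord

logger = logging.getLogger(__name__)

CLASSES = ("selective", "family_crossreactive", "promiscuous", "inactive")

#: default per-class hit ratios; family_crossreactive carries
#: (in-family, out-of-family) activity probabilities
DEFAULT_CLASS_HIT_RATIOS = {
    "selective": 0.02,
    "family_crossreactive": (0.7, 0.02),
    "promiscuous": 0.6,
    "inactive": 0.0005,
}

DEFAULT_CLASS_MIX = {
    "selective": 0.35,
    "family_crossreactive": 0.05,
    "promiscuous": 0.01,
    "inactive": 0.59,
}


@dataclass
class SyntheticConfig:
    """Generation parameters for a synthetic bioactivity world.

    ``participation`` is a distribution spec over the number of screened
    targets per compound: ("loguniform", lo, hi), ("uniform", lo, hi) or
    ("fixed", n); ``hi=None`` means the full target count.  ``p_true_active``
    is the nominal background true-active probability; the realised marginal
    is driven by the class mix and per-class hit ratios (see
    :meth:`implied_active_fraction`).
    """

    n_compounds: int = 1000
    n_targets: int = 200
    n_families: int = 10
    domains_per_target: tuple = (1, 3)
    p_true_active: float = 0.013
    flip_error_rate: float = 0.00698
    participation: tuple = ("loguniform", 1, None)
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    class_hit_ratios: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_HIT_RATIOS))
    planted_biclusters: list = field(default_factory=list)
    replicate_fraction: float = 0.16
    n_fingerprint_bits: int = 128
    seed: int = 0

    def __post_init__(self):
        for name in ("n_compounds", "n_targets", "n_families"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_true_active", "flip_error_rate", "replicate_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if set(self.class_mix) - set(CLASSES):
            raise ValueError(f"unknown classes in mix: "
                             f"{set(self.class_mix) - set(CLASSES)}")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix sums to {total}, expected 1")
        if any(p < 0 for p in self.class_mix.values()):
            raise ValueError("class_mix proportions must be non-negative")
        lo, hi = self.domains_per_target
        if not (1 <= lo <= hi):
            raise ValueError("domains_per_target must satisfy 1 <= lo <= hi")
        for n_r, n_c, dens in self.planted_biclusters:
            if n_r > self.n_compounds or n_c > self.n_targets:
                raise ValueError("planted bicluster exceeds matrix dimensions")
            if not (0.0 < dens <= 1.0):
                raise ValueError("planted density must lie in (0, 1]")

    def implied_active_fraction(self) -> float:
        """Expected true-active fraction among tested pairs under the class
        mix (before planting and observation error)."""
        fam_share = 1.0 / self.n_families
        total = 0.0
        for cls, prop in self.class_mix.items():
            theta = self.class_hit_ratios[cls]
            if cls == "family_crossreactive":
                p_in, p_out = theta
                theta = p_in * fam_share + p_out * (1.0 - fam_share)
            total += prop * theta
        return total


@dataclass
class SyntheticWorld:
    """A generated bioactivity world plus its ground truth."""

    config: SyntheticConfig
    activity_records: list
    truth: pd.DataFrame             # cid, compound_class, theta, family
    target_families: dict           # target_id -> family cluster id
    domain_map: dict                # target_id -> frozenset of domain ids
    planted_memberships: list       # list of (compound ids, target ids)
    label_sets: dict                # name -> set of compound ids
    fingerprints: pd.DataFrame      # cid index x bit columns

    def compound_ids(self) -> list:
        return list(self.truth["cid"])

    def target_ids(self) -> list:
        return sorted(self.target_families)

    def to_dir(self, out_dir) -> None:
        """Write the world as the TSV formats the pipeline reads."""
        from . import io as bio_io
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bio_io.write_activity_tsv(self.activity_records, out / "activity.tsv")
        bio_io.write_map_tsv(self.target_families, out / "cluster_map.tsv",
                             ("target_id", "cluster_id"))
        pairs = [(t, d) for t, doms in sorted(self.domain_map.items())
                 for d in sorted(doms)]
        bio_io.write_pairs_tsv(pairs, out / "domain_map.tsv",
                               ("target_id", "domain_id"))
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        for name, ids in sorted(self.label_sets.items()):
            bio_io.write_id_list(sorted(ids, key=str), out / f"labels_{name}.txt")
        bio_io.write_fingerprints(self.fingerprints, out / "fingerprints.tsv")


def plant_biclusters(
    active: np.ndarray,
    planted: Sequence[tuple],
    rng: Optional[np.random.Generator] = None,
    tested: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, list]:
    """Plant dense active blocks into a boolean activity matrix.

    Each planted spec ``(n_rows, n_cols, density)`` selects a random row and
    column subset and sets ``ceil(density * n_rows * n_cols)`` randomly chosen
    cells of the block active (and tested, when a tested mask is supplied),
    guaranteeing a block density of at least ``density``.  Overlapping blocks
    are allowed; every block's membership is recorded and returned.
    """
    rng = rng or np.random.default_rng(0)
    active = active.copy()
    memberships = []
    n_rows, n_cols = active.shape
    for n_r, n_c, dens in planted:
        if n_r > n_rows or n_c > n_cols:
            raise ValueError("planted block exceeds matrix dimensions")
        rows = np.sort(rng.choice(n_rows, size=n_r, replace=False))
        cols = np.sort(rng.choice(n_cols, size=n_c, replace=False))
        n_cells = n_r * n_c
        n_on = int(np.ceil(dens * n_cells))
        flat = rng.choice(n_cells, size=n_on, replace=False)
        block = active[np.ix_(rows, cols)]
        block.flat[flat] = True
        active[np.ix_(rows, cols)] = block
        if tested is not None:
            tblock = tested[np.ix_(rows, cols)]
            tblock.flat[flat] = True
            tested[np.ix_(rows, cols)] = tblock
        memberships.append((rows, cols))
    return active, memberships


def _participation_counts(spec, n_compounds, n_targets, rng) -> np.ndarray:
    kind, lo, hi = (spec + (None,))[:3] if len(spec) < 3 else spec
    hi = n_targets if hi is None else hi
    if kind == "fixed":
        return np.full(n_compounds, int(lo))
    if kind == "uniform":
        return rng.integers(lo, hi + 1, size=n_compounds)
    if kind == "loguniform":
        draws = np.exp(rng.uniform(np.log(lo), np.log(hi + 1), n_compounds))
        return np.clip(draws.astype(int), lo, hi)
    raise ValueError(f"unknown participation spec {spec!r}")


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Generate a seeded synthetic world; byte-identical for a fixed config."""
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_targets, rng_classes, rng_particip, rng_truth, rng_plant, \
        rng_obs, rng_labels = (np.random.default_rng(s) for s in streams)

    n_c, n_t, n_f = config.n_compounds, config.n_targets, config.n_families
    compound_ids = [f"C{i:06d}" for i in range(n_c)]
    target_ids = [f"T{j:04d}" for j in range(n_t)]

    # families: random assignment, but every family gets at least one target
    fam_of_target = rng_targets.integers(n_f, size=n_t)
    fam_of_target[:n_f] = np.arange(n_f)
    target_families = {target_ids[j]: f"F{fam_of_target[j]:03d}"
                       for j in range(n_t)}

    # domains: a family-core domain shared by all members (so sequence-similar
    # targets always share a domain) plus extras from a family-specific pool
    lo_d, hi_d = config.domains_per_target
    pool_size = 5
    domain_map = {}
    for j, tid in enumerate(target_ids):
        fam = fam_of_target[j]
        doms = {f"D{fam:03d}_core"}
        n_extra = int(rng_targets.integers(lo_d, hi_d + 1)) - 1
        if n_extra > 0:
            extras = rng_targets.choice(pool_size, size=min(n_extra, pool_size),
                                        replace=False)
            doms |= {f"D{fam:03d}_x{e}" for e in extras}
        domain_map[tid] = frozenset(doms)

    # compound classes and per-class activity parameters
    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    cls_idx = rng_classes.choice(len(classes), size=n_c, p=probs / probs.sum())
    compound_class = np.array(classes, dtype=object)[cls_idx]
    assigned_family = rng_classes.integers(n_f, size=n_c)  # used by crossreactive
    fam_share = 1.0 / n_f
    theta = np.empty(n_c)
    for i in range(n_c):
        hr = config.class_hit_ratios[compound_class[i]]
        if compound_class[i] == "family_crossreactive":
            p_in, p_out = hr
            theta[i] = p_in * fam_share + p_out * (1.0 - fam_share)
        else:
            theta[i] = hr

    # tested mask from the participation distribution
    n_screened = _participation_counts(config.participation, n_c, n_t,
                                       rng_particip)
    tested = np.zeros((n_c, n_t), dtype=bool)
    for i in range(n_c):
        cols = rng_particip.choice(n_t, size=n_screened[i], replace=False)
        tested[i, cols] = True

    # true activity per tested pair
    p_active = np.empty((n_c, n_t))
    for i in range(n_c):
        cls = compound_class[i]
        hr = config.class_hit_ratios[cls]
        if cls == "family_crossreactive":
            p_in, p_out = hr
            p_active[i] = np.where(fam_of_target == assigned_family[i],
                                   p_in, p_out)
        else:
            p_active[i] = hr
    active = tested & (rng_truth.random((n_c, n_t)) < p_active)

    # planted dense biclusters (cells become tested and active)
    active, planted_idx = plant_biclusters(
        active, config.planted_biclusters, rng=rng_plant, tested=tested)
    planted_memberships = [
        ([compound_ids[i] for i in rows], [target_ids[j] for j in cols])
        for rows, cols in planted_idx]

    # observation: one measurement per tested pair, a second for a replicated
    # fraction; each measurement flips the truth with probability e
    e = config.flip_error_rate
    records = []
    replicate = rng_obs.random((n_c, n_t)) < config.replicate_fraction
    flips1 = rng_obs.random((n_c, n_t)) < e
    flips2 = rng_obs.random((n_c, n_t)) < e
    ii, jj = np.nonzero(tested)
    for i, j in zip(ii, jj):
        truth_ij = active[i, j]
        obs1 = truth_ij ^ flips1[i, j]
        records.append(ActivityRecord(
            assay_id=f"A{j:04d}_0", compound_id=compound_ids[i],
            target_id=target_ids[j],
            outcome="active" if obs1 else "inactive"))
        if replicate[i, j]:
            obs2 = truth_ij ^ flips2[i, j]
            records.append(ActivityRecord(
                assay_id=f"A{j:04d}_1", compound_id=compound_ids[i],
                target_id=target_ids[j],
                outcome="active" if obs2 else "inactive"))

    # label sets emulating external compound annotations: an FDA-like set
    # enriched for cross-reactive and promiscuous compounds, a PAINS-like set
    # enriched in the middle promiscuity range, an aggregator-like set
    # enriched among the most promiscuous
    enrich = {
        "fda": {"selective": 0.02, "family_crossreactive": 0.30,
                "promiscuous": 0.30, "inactive": 0.005},
        "pains": {"selective": 0.03, "family_crossreactive": 0.25,
                  "promiscuous": 0.35, "inactive": 0.01},
        "aggregator": {"selective": 0.005, "family_crossreactive": 0.02,
                       "promiscuous": 0.60, "inactive": 0.001},
    }
    label_sets = {}
    for name, rates in enrich.items():
        draw = rng_labels.random(n_c)
        rate = np.array([rates[c] for c in compound_class])
        label_sets[name] = {compound_ids[i] for i in np.flatnonzero(draw < rate)}

    # fingerprints: random binary vectors with group-correlated bits; groups
    # follow the lowest planted bicluster, else class+family, so structurally
    # coherent compound sets exist without simulating chemistry
    n_bits = config.n_fingerprint_bits
    group = np.array([f"{compound_class[i]}:{assigned_family[i]}"
                      for i in range(n_c)], dtype=object)
    for b_idx, (rows, _) in enumerate(planted_idx):
        for i in rows:
            if not str(group[i]).startswith("bicluster"):
                group[i] = f"bicluster{b_idx}"
    prototypes = {}
    fps = np.zeros((n_c, n_bits), dtype=np.int8)
    for i in range(n_c):
        g = group[i]
        if g not in prototypes:
            prototypes[g] = rng_labels.random(n_bits) < 0.3
        noise = rng_labels.random(n_bits) < 0.05
        fps[i] = (prototypes[g] ^ noise).astype(np.int8)
    fingerprints = pd.DataFrame(fps, index=pd.Index(compound_ids, name="cid"))

    truth = pd.DataFrame({
        "cid": compound_ids,
        "compound_class": compound_class,
        "theta": theta,
        "family": [f"F{assigned_family[i]:03d}" for i in range(n_c)],
        "n_screened": n_screened,
    })
    return SyntheticWorld(
        config=config,
        activity_records=records,
        truth=truth,
        target_families=target_families,
        domain_map=domain_map,
        planted_memberships=planted_memberships,
        label_sets=label_sets,
        fingerprints=fingerprints,
    )
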