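"""Selectivity counting, Table-style binning, distribution fits, rank tests."""

import numpy as np
import pytest

from bioprofile import (ActivityRecord, ClusterMap, DomainMap,
                        SelectivityProfile, bin_domains_by_median_selectivity,
                        build_matrix, domain_selectivity,
                        downsample_to_match_median, fit_stretched_exponential,
                        fit_with_comparators, rank_sum_one_sided,
                        selectivity_profiles)
from bioprofile.store import ACTIVE


def bfs_components(nodes, edges):
    """Independent component count by breadth-first search."""
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen, n_comp = set(), 0
    for start in nodes:
        if start in seen:
            continue
        n_comp += 1
        frontier = [start]
        while frontier:
            node = frontier.pop()
            if node in seen:
                continue
            seen.add(node)
            frontier.extend(adj[node] - seen)
    return n_comp


class TestDomainSelectivity:
    def test_four_of_five_targets_share_a_domain(self):
        """Five active targets, four sharing one Pfam domain: two components."""
        dmap = DomainMap({f"t{i}": {"shared"} for i in range(4)}
                         | {"t4": {"other"}})
        assert domain_selectivity([f"t{i}" for i in range(5)], dmap) == 2

    def test_all_targets_one_domain(self):
        dmap = DomainMap({f"t{i}": {"d"} for i in range(7)})
        assert domain_selectivity(dmap.target_to_domains, dmap) == 1

    def test_targets_without_domains_are_isolated(self):
        dmap = DomainMap({"t0": {"d"}, "t1": {"d"}})
        assert domain_selectivity(["t0", "t1", "bare1", "bare2"], dmap) == 3

    def test_matches_bfs_component_oracle(self, rng):
        targets = [f"t{i}" for i in range(12)]
        domains = [f"d{i}" for i in range(6)]
        for _ in range(50):
            dmap = DomainMap({
                t: {d for d in domains if rng.random() < 0.25} for t in targets})
            active = [t for t in targets if rng.random() < 0.6]
            edges = [(a, b) for i, a in enumerate(active)
                     for b in active[i + 1:]
                     if dmap.domains(a) & dmap.domains(b)]
            assert domain_selectivity(active, dmap) == \
                bfs_components(active, edges)


class TestSelectivityProfiles:
    def test_nested_counts_for_clustered_targets(self):
        records = [ActivityRecord("a", "c1", f"t{i}", "active")
                   for i in range(3)]
        matrix = build_matrix(records)  # identity columns = targets
        cmap = ClusterMap({f"t{i}": "cl1" for i in range(3)})
        dmap = DomainMap({f"t{i}": {"d"} for i in range(3)})
        (p,) = selectivity_profiles(matrix, cmap, dmap)
        assert (p.target_selectivity, p.cluster_selectivity,
                p.domain_selectivity) == (3, 1, 1)

    def test_inactive_compound_profile_is_zero(self):
        records = [ActivityRecord("a", "c1", f"t{i}", "inactive")
                   for i in range(4)]
        matrix = build_matrix(records)
        (p,) = selectivity_profiles(matrix, ClusterMap({}), DomainMap({}))
        assert (p.n_screened, p.target_selectivity, p.cluster_selectivity,
                p.domain_selectivity) == (4, 0, 0, 0)

    def test_matches_independent_recomputation_from_records(
            self, small_world, small_world_maps):
        cmap, dmap = small_world_maps
        matrix = build_matrix(small_world.activity_records)
        profiles = selectivity_profiles(matrix, cmap, dmap)
        by_cid = {p.compound_id: p for p in profiles}
        # recompute from raw records for a sample of compounds
        cids = sorted(by_cid)[:25]
        for cid in cids:
            screened = {r.target_id for r in small_world.activity_records
                        if r.compound_id == cid}
            active = {r.target_id for r in small_world.activity_records
                      if r.compound_id == cid and r.outcome == "active"}
            p = by_cid[cid]
            assert p.n_screened == len(screened)
            assert p.target_selectivity == len(active)
            assert p.cluster_selectivity == len(
                {small_world.target_families[t] for t in active})

    def test_nesting_invariant_on_synthetic_world(self, small_world,
                                                  small_world_maps):
        cmap, dmap = small_world_maps
        matrix = build_matrix(small_world.activity_records)
        for p in selectivity_profiles(matrix, cmap, dmap):
            assert (p.domain_selectivity <= p.cluster_selectivity
                    <= p.target_selectivity <= p.n_screened)

    def test_unknown_compound_raises(self):
        matrix = build_matrix([ActivityRecord("a", "c1", "t1", "active")])
        with pytest.raises(KeyError):
            selectivity_profiles(matrix, ClusterMap({}), DomainMap({}),
                                 compounds=["ghost"])


def make_profile(cid, dom_sel):
    return SelectivityProfile(compound_id=cid, n_screened=dom_sel + 5,
                              target_selectivity=dom_sel,
                              cluster_selectivity=dom_sel,
                              domain_selectivity=dom_sel)


class TestDomainBinning:
    def test_domain_with_too_few_actives_excluded(self):
        profiles = [make_profile(f"c{i}", 3) for i in range(9)]
        binned = bin_domains_by_median_selectivity(
            {"dom": {p.compound_id for p in profiles}}, profiles)
        assert "dom" not in binned

    def test_constant_median_lands_in_low_bin(self):
        profiles = [make_profile(f"c{i}", 3) for i in range(11)]
        binned = bin_domains_by_median_selectivity(
            {"dom": {p.compound_id for p in profiles}}, profiles)
        assert binned["dom"] == (2, 4)

    def test_median_arithmetic_selects_bin(self):
        sels = [2, 5, 7, 8, 9, 11, 12, 13, 14, 15, 20]
        profiles = [make_profile(f"c{i}", s) for i, s in enumerate(sels)]
        binned = bin_domains_by_median_selectivity(
            {"dom": {p.compound_id for p in profiles}}, profiles)
        assert binned["dom"] == (11, 13.5)  # median of 11 values is 11


class TestStretchedExponentialFit:
    def test_exact_recovery_on_noiseless_data(self):
        x = np.arange(1, 31, dtype=float)
        p = np.exp(-((x / 2.0) ** 0.7))
        fit = fit_stretched_exponential(x, p)
        assert fit.c == pytest.approx(0.7, abs=1e-6)
        assert fit.x0 == pytest.approx(2.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_reduces_to_pure_exponential_at_c_equal_one(self):
        x = np.arange(1, 25, dtype=float)
        p = np.exp(-x / 3.0)
        fits = fit_with_comparators(x, p)
        assert fits.stretched.c == pytest.approx(1.0, abs=1e-6)
        assert abs(fits.stretched.r_squared - fits.exponential_r_squared) < 1e-9

    def test_recovery_under_multiplicative_log_noise(self):
        rng = np.random.default_rng(11)
        x = np.arange(1, 31, dtype=float)
        log_p = -((x / 2.0) ** 0.7) + rng.normal(0.0, 0.05, size=x.size)
        fit = fit_stretched_exponential(x, np.exp(log_p))
        assert fit.c == pytest.approx(0.7, rel=0.05)
        assert fit.x0 == pytest.approx(2.0, rel=0.05)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_stretched_exponential([1.0, 2.0], [0.5, 0.2])


class TestRankSum:
    def test_complete_separation_gives_maximal_w(self):
        w, p = rank_sum_one_sided([10, 11, 12], [1, 2, 3])
        assert w == 9.0
        assert p < 0.06

    def test_identical_groups_centre_p(self):
        vals = list(range(1, 9))
        _, p = rank_sum_one_sided(vals, vals)
        assert p == pytest.approx(0.5, abs=0.05)

    def test_w_matches_pairwise_win_count(self, rng):
        for _ in range(40):
            a = rng.integers(0, 6, size=int(rng.integers(2, 9)))
            b = rng.integers(0, 6, size=int(rng.integers(2, 9)))
            w, _ = rank_sum_one_sided(a, b)
            oracle = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
            assert w == pytest.approx(oracle)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_one_sided([], [1])


class TestDownsample:
    @staticmethod
    def participation(records, group):
        per = {}
        for r in records:
            per.setdefault(r.compound_id, set()).add(r.target_id)
        return [len(per.get(c, set())) for c in group]

    @staticmethod
    def make_records(spec):
        return [ActivityRecord("a", cid, f"t{j}", "inactive")
                for cid, n in spec.items() for j in range(n)]

    def test_no_removals_when_medians_match(self):
        records = self.make_records({"a1": 5, "b1": 5})
        reduced, removed = downsample_to_match_median(records, ["a1"], ["b1"])
        assert removed == set() and len(reduced) == len(records)

    def test_median_reduced_to_target(self):
        records = self.make_records(
            {"a1": 50, "a2": 60, "a3": 70, "b1": 40, "b2": 40, "b3": 40})
        reduced, _ = downsample_to_match_median(
            records, ["a1", "a2", "a3"], ["b1", "b2", "b3"], seed=5)
        med_a = np.median(self.participation(reduced, ["a1", "a2", "a3"]))
        assert med_a <= 40

    def test_same_seed_same_removals(self):
        records = self.make_records({"a1": 30, "a2": 20, "b1": 10})
        _, r1 = downsample_to_match_median(records, ["a1", "a2"], ["b1"],
                                           seed=9)
        _, r2 = downsample_to_match_median(records, ["a1", "a2"], ["b1"],
                                           seed=9)
        assert r1 == r2 and len(r1) > 0
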