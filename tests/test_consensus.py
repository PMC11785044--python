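import dataclasses
import itertools

import numpy as np
import pytest

from conftest import make_program
from senprog import (ConsensusParams, cluster_programs, greedy_select,
                     jaccard_index, robust_filter, signature_genes)
from senprog.consensus import linkage_to_newick, program_linkage, rank_programs
from senprog.nmf import ProgramCollection

GENES = [f"g{i:03d}" for i in range(300)]


def block(start, n=50):
    return GENES[start:start + n]


def mix(a_start, n_from_a, b_start, total=50):
    """Gene list with ``n_from_a`` genes from block a, rest from block b."""
    return GENES[a_start:a_start + n_from_a] + GENES[b_start:b_start + (total - n_from_a)]


class TestJaccard:
    def test_identical_sets(self):
        assert jaccard_index(block(0), block(0)) == 1.0

    def test_disjoint_sets(self):
        assert jaccard_index(block(0), block(50)) == 0.0

    def test_partial_overlap_set_arithmetic(self):
        # 50-gene lists sharing 35: 35 / (50 + 50 - 35)
        a, b = block(0), mix(0, 35, 100)
        assert jaccard_index(a, b) == pytest.approx(35 / 65)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            jaccard_index([], block(0))

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.choice(GENES, rng.integers(5, 60), replace=False)
            b = rng.choice(GENES, rng.integers(5, 60), replace=False)
            j = jaccard_index(a, b)
            assert j == jaccard_index(b, a)
            assert 0.0 <= j <= 1.0


class TestRobustFilter:
    def collection(self, intra_shared, inter_shared):
        """Candidate program plus one same-line (other-K) and one other-line partner."""
        cand = make_program("L1", 6, 0, block(0))
        same = make_program("L1", 7, 0, mix(0, intra_shared, 100))
        other = make_program("L2", 6, 0, mix(0, inter_shared, 200))
        return ProgramCollection([cand, same, other]), cand

    def test_boundary_inclusive_at_35_and_10(self):
        coll, cand = self.collection(35, 10)
        kept = robust_filter(coll, ConsensusParams())
        assert cand.key in kept

    def test_34_intra_shared_genes_removed(self):
        coll, cand = self.collection(34, 10)
        kept = robust_filter(coll, ConsensusParams())
        assert cand.key not in kept

    def test_9_inter_shared_genes_removed(self):
        coll, cand = self.collection(35, 9)
        kept = robust_filter(coll, ConsensusParams())
        assert cand.key not in kept

    def test_same_k_does_not_satisfy_cross_rank_criterion(self):
        cand = make_program("L1", 6, 0, block(0))
        twin = make_program("L1", 6, 1, block(0))           # same K
        other = make_program("L2", 6, 0, mix(0, 20, 200))
        kept = robust_filter(ProgramCollection([cand, twin, other]), ConsensusParams())
        assert cand.key not in kept

    def test_empty_collection(self):
        assert len(robust_filter(ProgramCollection(), ConsensusParams())) == 0

    def test_single_line_warns_and_retains_nothing(self):
        coll = ProgramCollection([make_program("L1", 6, 0, block(0)),
                                  make_program("L1", 7, 0, block(0))])
        with pytest.warns(UserWarning, match="single line"):
            kept = robust_filter(coll, ConsensusParams())
        assert len(kept) == 0

    def test_monotone_in_thresholds(self, sim_expr):
        from senprog import center_and_clip, run_nmf_range
        coll = ProgramCollection()
        for line in dict.fromkeys(sim_expr.line_labels):
            idx = np.flatnonzero(sim_expr.line_labels == line)
            coll.extend(run_nmf_range(center_and_clip(sim_expr.subset_cells(idx)),
                                      ks=(4, 5), seed=0, line_id=str(line)))
        base = {p.key for p in robust_filter(coll, ConsensusParams())}
        stricter = {p.key for p in robust_filter(
            coll, ConsensusParams(intra_line_overlap_min=40,
                                  inter_line_overlap_min=15))}
        assert stricter <= base

    def test_planted_programs_survive_line_specific_removed(self, sim_expr, sim_bundle):
        from senprog import center_and_clip, run_nmf_range
        _, _, truth = sim_bundle
        coll = ProgramCollection()
        for line in dict.fromkeys(sim_expr.line_labels):
            idx = np.flatnonzero(sim_expr.line_labels == line)
            coll.extend(run_nmf_range(center_and_clip(sim_expr.subset_cells(idx)),
                                      seed=0, line_id=str(line)))
        kept = robust_filter(coll, ConsensusParams())
        shared = set(truth.program_genes["shared"])
        specific = set(truth.program_genes["specific"])
        assert any(len(shared & p.gene_set) >= 34 for p in kept)
        assert not any(len(specific & p.gene_set) >= 34 for p in kept)


def greedy_oracle(programs, redundancy_max=10):
    """Literal re-simulation of the ranked scan for cross-checking."""
    def stat(p):
        js = [jaccard_index(p.genes, q.genes)
              for q in programs if q.line_id != p.line_id]
        return max(js, default=0.0)

    ranked = sorted(programs, key=lambda p: (-stat(p), p.key))
    chosen = []
    for p in ranked:
        if all(not (s.line_id == p.line_id
                    and len(set(p.genes) & set(s.genes)) > redundancy_max)
               for s in chosen):
            chosen.append(p)
    return [p.key for p in chosen]


class TestGreedySelect:
    def test_single_program_selected(self):
        coll = ProgramCollection([make_program("L1", 6, 0, block(0))])
        assert len(greedy_select(coll, ConsensusParams())) == 1

    def test_redundant_same_line_program_excluded_strictly_above_10(self):
        # rank 1 and rank 2 share 11 genes -> only rank 1 kept
        p1 = make_program("L1", 6, 0, block(0))
        p2 = make_program("L1", 7, 0, mix(0, 11, 100))
        partner = make_program("L2", 6, 0, block(0))        # makes p1 rank first
        out = greedy_select(ProgramCollection([p1, p2, partner]), ConsensusParams())
        keys = [p.key for p in out]
        assert p1.key in keys and p2.key not in keys

    def test_exactly_10_shared_genes_not_redundant(self):
        p1 = make_program("L1", 6, 0, block(0))
        p2 = make_program("L1", 7, 0, mix(0, 10, 100))
        partner = make_program("L2", 6, 0, block(0))
        out = greedy_select(ProgramCollection([p1, p2, partner]), ConsensusParams())
        assert {p1.key, p2.key} <= {p.key for p in out}

    def test_matches_exhaustive_scan_on_random_instances(self):
        rng = np.random.default_rng(42)
        for trial in range(60):
            n = int(rng.integers(1, 7))
            programs = []
            for i in range(n):
                line = f"L{rng.integers(1, 4)}"
                k = int(rng.integers(4, 8))
                genes = tuple(rng.choice(GENES[:120], 50, replace=False))
                key = (line, k, i)
                programs.append(make_program(line, k, i, genes))
            coll = ProgramCollection(programs)
            got = [p.key for p in greedy_select(coll, ConsensusParams())]
            assert got == greedy_oracle(programs)

    def test_output_pairwise_non_redundant_within_line(self, sim_expr):
        from senprog import center_and_clip, run_nmf_range
        coll = ProgramCollection()
        for line in dict.fromkeys(sim_expr.line_labels):
            idx = np.flatnonzero(sim_expr.line_labels == line)
            coll.extend(run_nmf_range(center_and_clip(sim_expr.subset_cells(idx)),
                                      ks=(5, 6), seed=0, line_id=str(line)))
        params = ConsensusParams()
        out = list(greedy_select(robust_filter(coll, params), params))
        for a, b in itertools.combinations(out, 2):
            if a.line_id == b.line_id:
                assert len(a.gene_set & b.gene_set) <= 10


class TestClusterPrograms:
    def test_identical_programs_merge_at_distance_zero(self):
        a = make_program("L1", 6, 0, block(0))
        b = make_program("L2", 6, 0, block(0))
        c = make_program("L1", 7, 0, block(100))
        coll = ProgramCollection([a, b, c])
        gps = cluster_programs(coll, ConsensusParams(n_clusters=2))
        by_member = {m.key: gp.gp_id for gp in gps for m in gp.members}
        assert by_member[a.key] == by_member[b.key] != by_member[c.key]

    def test_merge_heights_match_hand_computed_average_linkage(self):
        # J(A,B)=3/5, J(A,C)=J(B,C)=1/7 -> d(AB)=0.4, then avg height 6/7
        a = make_program("L1", 6, 0, ["g1", "g2", "g3", "g4"])
        b = make_program("L2", 6, 0, ["g1", "g2", "g3", "g5"])
        c = make_program("L3", 6, 0, ["g1", "g6", "g7", "g8"])
        Z = program_linkage(ProgramCollection([a, b, c]))
        assert Z[0, 2] == pytest.approx(1 - 3 / 5)
        assert Z[1, 2] == pytest.approx((6 / 7 + 6 / 7) / 2)

    def test_cluster_count_equal_to_programs_gives_singletons(self):
        progs = [make_program("L1", 6, i, block(60 * i, 40)) for i in range(3)]
        gps = cluster_programs(ProgramCollection(progs), ConsensusParams(n_clusters=3))
        assert sorted(len(gp.members) for gp in gps) == [1, 1, 1]

    def test_too_many_clusters_rejected(self):
        progs = [make_program("L1", 6, 0, block(0))]
        with pytest.raises(ValueError, match="n_clusters"):
            cluster_programs(ProgramCollection(progs), ConsensusParams(n_clusters=7))

    def test_newick_export_parses(self):
        progs = [make_program("L1", 6, i, block(60 * i, 40)) for i in range(3)]
        Z = program_linkage(ProgramCollection(progs))
        nwk = linkage_to_newick(Z, [p.name for p in progs])
        assert nwk.endswith(";") and nwk.count("(") == 2


class TestSignatureGenes:
    def members(self, gene_lists):
        return [make_program("L1", 6, i, g) for i, g in enumerate(gene_lists)]

    def test_gene_in_40_percent_of_five_members_included(self):
        lists = [["a", "x1"], ["a", "x2"], ["b", "x3"], ["b", "x4"], ["c", "x5"]]
        sig = signature_genes(self.members(lists), min_fraction=0.40)
        assert "a" in sig and "b" in sig

    def test_gene_in_one_of_five_members_excluded(self):
        lists = [["a", "x1"], ["b", "x2"], ["b", "x3"], ["b", "x4"], ["b", "x5"]]
        sig = signature_genes(self.members(lists), min_fraction=0.40)
        assert "a" not in sig

    def test_single_member_signature_is_its_gene_list(self):
        [m] = self.members([["z", "y", "x"]])
        assert set(signature_genes([m], 0.40)) == {"x", "y", "z"}

    def test_ordered_by_occurrence_then_gene_id(self):
        lists = [["a", "b"], ["a", "c"], ["a", "b", "c"]]
        sig = signature_genes(self.members(lists), min_fraction=0.5)
        assert sig == ["a", "b", "c"]


class TestRanking:
    def test_rank_statistic_orders_by_cross_line_similarity(self):
        strong = make_program("L1", 6, 0, block(0))
        weak = make_program("L1", 7, 0, block(100))
        partner = make_program("L2", 6, 0, mix(0, 40, 200))
        ranked = rank_programs(ProgramCollection([weak, strong, partner]),
                               ConsensusParams())
        assert ranked[0].key == strong.key or ranked[0].key == partner.key
        assert ranked.index(strong) < ranked.index(weak)
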