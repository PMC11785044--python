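import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_program
from senprog import (MPReference, annotate_gps, detection_frequency,
                     fdr_adjust, hypergeom_overlap, mp_similarity,
                     permutation_thresholds, select_representative_genes)
from senprog.consensus import GPCluster
from senprog.scoring import score_programs
from senprog.preprocessing import ExpressionMatrix


def small_expr(seed=0, n_genes=80, n_cells=120):
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(
        rng.uniform(0, 4, (n_genes, n_cells)),
        np.array([f"g{i:03d}" for i in range(n_genes)], dtype=object),
        np.array([f"c{i}" for i in range(n_cells)], dtype=object),
        np.array(["line0"] * n_cells, dtype=object))


class TestMPSimilarity:
    def _scored(self, expr, sets):
        return score_programs(expr, sets, n_sets=50, n_bins=10, seed=0)

    def test_identical_sets_have_unit_jaccard_and_correlation(self):
        expr = small_expr()
        genes = [str(g) for g in expr.gene_ids[:20]]
        gp = GPCluster("GP1", [make_program("L1", 6, 0, genes)], list(genes))
        scores = self._scored(expr, {"GP1": genes, "MP1": genes})
        mj, mc = mp_similarity(gp, "MP1", genes, scores)
        assert mj == 1.0
        assert mc == pytest.approx(1.0)

    def test_disjoint_sets_near_zero_statistics(self):
        expr = small_expr(1)
        a = [str(g) for g in expr.gene_ids[:20]]
        b = [str(g) for g in expr.gene_ids[40:60]]
        gp = GPCluster("GP1", [make_program("L1", 6, 0, a)], list(a))
        scores = self._scored(expr, {"GP1": a, "MP1": b})
        mj, mc = mp_similarity(gp, "MP1", b, scores)
        assert mj == 0.0
        assert abs(mc) < 0.5


class TestPermutationThresholds:
    def test_degenerate_null_threshold_equals_the_constant(self):
        # a GP spanning the whole universe: every permuted list is the full
        # universe, so the pooled jaccard null is constant
        expr = small_expr(2, n_genes=50)
        genes = [str(g) for g in expr.gene_ids]
        gp = GPCluster("GP1", [make_program("L1", 6, 0, genes)], list(genes))
        mp_genes = genes[:10]
        mp = MPReference.from_gmt({"MP1": mp_genes}, universe=genes)
        scores = score_programs(expr, {"MP1": mp_genes}, n_sets=30, n_bins=5, seed=0)
        thr = permutation_thresholds([gp], mp, expr, scores, n_perm=5, seed=1,
                                     n_background=20, n_bins=5)
        assert thr.jaccard == pytest.approx(10 / 50)
        assert np.allclose(thr.null_jaccard, 10 / 50)

    def test_planted_gp_flagged_unrelated_not(self, null_expr):
        rng = np.random.default_rng(3)
        genes = [str(g) for g in rng.choice(null_expr.gene_ids, 40, replace=False)]
        other = [str(g) for g in rng.choice(
            np.setdiff1d(null_expr.gene_ids, genes), 40, replace=False)]
        gp = GPCluster("GP1", [make_program("L1", 6, 0, genes)], list(genes))
        universe = set(map(str, null_expr.gene_ids))
        mp = MPReference.from_gmt({"MP_same": genes, "MP_other": other},
                                  universe=universe)
        scores = score_programs(null_expr, {"GP1": genes, "MP_same": genes,
                                            "MP_other": other},
                                n_sets=100, seed=4)
        table = annotate_gps([gp], mp, null_expr, scores, n_perm=20,
                             confidence=0.95, seed=5, n_background=50)
        res = table.set_index("mp_id")
        assert res.loc["MP_same", "significant"]
        assert not res.loc["MP_other", "significant"]
        assert res.loc["MP_same", "fdr_q"] < 1e-9

    def test_same_seed_identical_thresholds(self):
        expr = small_expr(6)
        genes = [str(g) for g in expr.gene_ids[:15]]
        gp = GPCluster("GP1", [make_program("L1", 6, 0, genes)], list(genes))
        mp = MPReference.from_gmt({"MP1": genes}, universe=set(map(str, expr.gene_ids)))
        scores = score_programs(expr, {"MP1": genes}, n_sets=30, n_bins=8, seed=0)
        t1 = permutation_thresholds([gp], mp, expr, scores, n_perm=4, seed=9,
                                    n_background=20, n_bins=8)
        t2 = permutation_thresholds([gp], mp, expr, scores, n_perm=4, seed=9,
                                    n_background=20, n_bins=8)
        assert t1.jaccard == t2.jaccard
        assert t1.correlation == t2.correlation

    def test_threshold_increases_with_confidence(self):
        expr = small_expr(7)
        genes = [str(g) for g in expr.gene_ids[:15]]
        gp = GPCluster("GP1", [make_program("L1", 6, 0, genes)], list(genes))
        mp = MPReference.from_gmt({"MP1": [str(g) for g in expr.gene_ids[20:40]]},
                                  universe=set(map(str, expr.gene_ids)))
        scores = score_programs(expr, {"MP1": [str(g) for g in expr.gene_ids[20:40]]},
                                n_sets=30, n_bins=8, seed=0)
        lo = permutation_thresholds([gp], mp, expr, scores, n_perm=10, seed=2,
                                    confidence=0.5, n_background=20, n_bins=8)
        hi = permutation_thresholds([gp], mp, expr, scores, n_perm=10, seed=2,
                                    confidence=0.99, n_background=20, n_bins=8)
        assert hi.jaccard >= lo.jaccard
        assert hi.correlation >= lo.correlation


def hypergeom_oracle(n_a, n_b, overlap, universe):
    """Exhaustive tail sum over all feasible overlap counts."""
    total = 0.0
    for k in range(overlap, min(n_a, n_b) + 1):
        if n_b - k > universe - n_a:
            continue
        total += (math.comb(n_a, k) * math.comb(universe - n_a, n_b - k)
                  / math.comb(universe, n_b))
    return total


class TestHypergeomOverlap:
    def test_full_overlap_closed_form(self):
        a = [f"g{i}" for i in range(10)]
        p = hypergeom_overlap(a, a, universe_size=100)
        assert p == pytest.approx(1 / math.comb(100, 10))

    def test_no_overlap_in_large_universe_near_one(self):
        a = [f"a{i}" for i in range(3)]
        b = [f"b{i}" for i in range(3)]
        assert hypergeom_overlap(a, b, universe_size=10_000) == pytest.approx(1.0, abs=1e-3)

    def test_matches_exhaustive_enumeration_on_small_universes(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            universe = int(rng.integers(5, 26))
            n_a = int(rng.integers(1, universe + 1))
            n_b = int(rng.integers(1, universe + 1))
            genes = [f"g{i}" for i in range(universe)]
            a = list(rng.choice(genes, n_a, replace=False))
            b = list(rng.choice(genes, n_b, replace=False))
            k = len(set(a) & set(b))
            got = hypergeom_overlap(a, b, universe)
            assert got == pytest.approx(hypergeom_oracle(n_a, n_b, k, universe), rel=1e-9)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_overlap([f"g{i}" for i in range(30)], ["g0"], universe_size=20)


class TestFDRAdjust:
    def test_equal_p_values_unchanged(self):
        assert np.allclose(fdr_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_bh_arithmetic_by_hand(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_its_own_q(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_never_below_raw_p_and_monotone_in_sorted_order(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0, 1, 40)
        q = fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestRepresentativeGenes:
    SASP = pd.DataFrame(
        {"Fibro RAS": [2.5, 1.9, np.nan, 3.0],
         "Epi IR": [0.5, 1.5, 1.0, np.nan]},
        index=pd.Index(["Anxa1", "Ecm1", "Il1rn", "Cxcl5"], name="gene"))

    def test_high_fold_change_and_full_detection_selected(self):
        det = pd.Series(1.0, index=["Anxa1", "Ecm1", "Il1rn", "Cxcl5"])
        out = select_representative_genes(["Anxa1", "Ecm1"], self.SASP, det)
        assert list(out["gene"]) == ["Anxa1"]
        assert out.iloc[0]["sasp_route"]

    def test_fold_change_below_threshold_not_selected(self):
        det = pd.Series(1.0, index=self.SASP.index)
        out = select_representative_genes(["Ecm1"], self.SASP, det)  # max fc 1.9
        assert out.empty

    def test_incomplete_detection_blocks_sasp_route(self):
        det = pd.Series({"Anxa1": 2 / 3})
        out = select_representative_genes(["Anxa1"], self.SASP, det)
        assert out.empty

    def test_companion_set_adds_genes_missing_from_sasp(self):
        det = pd.Series(1.0, index=self.SASP.index)
        out = select_representative_genes(
            ["Anxa1", "Cxcl1", "Cldn4"], self.SASP, det,
            companion_sets={"EpiSen": ["Cxcl1", "Cldn4", "Krt6a"]})
        got = out.set_index("gene")
        assert set(got.index) == {"Anxa1", "Cxcl1", "Cldn4"}
        assert got.loc["Cxcl1", "companion_route"]
        assert not got.loc["Cxcl1", "sasp_route"]


class TestDetectionFrequency:
    def test_per_line_fraction_of_lines_detected(self, sim_bundle):
        _, counts, _ = sim_bundle
        freq = detection_frequency(counts, mode="per_line")
        assert freq.min() >= 0 and freq.max() <= 1
        seen_everywhere = counts.values.sum(axis=1) > 3000
        assert np.all(freq[seen_everywhere] == 1.0)
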