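"""Annotation of consensus programs against reference meta-programs and SASP.

Consensus gene programs (GPs) are compared to curated reference
meta-programs (MPs) by two statistics: the mean Jaccard index between each
constituent NMF program's top-gene list and the MP, and the Pearson
correlation of per-cell GP and MP scores. Significance thresholds come from
permutation: constituent gene lists are replaced by uniform random same-size
draws from the gene universe, the permuted statistics are pooled across all
(GP, MP, permutation) triples, and the configured confidence quantile
(default 99.9%) of each pooled null is the threshold. Gene-set overlaps are
additionally tested with the upper-tail hypergeometric distribution and
Benjamini-Hochberg FDR control.

The representative-gene selection mirrors the secreted-senescence use case:
from a GP's gene list, keep genes whose secretion log2 fold-change exceeds
2 in at least one senescence condition of a SASP (senescence-associated
secretory phenotype) table AND whose detection frequency equals 1, then add
GP genes shared with any companion program (route B).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .consensus import GPCluster, jaccard_index
from .preprocessing import CountMatrix, ExpressionMatrix
from .scoring import ScoreMatrix, build_background_sets, score_cells

__all__ = [
    "MPReference",
    "PermutationThresholds",
    "mp_similarity",
    "permutation_thresholds",
    "hypergeom_overlap",
    "fdr_adjust",
    "annotate_gps",
    "detection_frequency",
    "read_sasp_table",
    "select_representative_genes",
]


@dataclass
class MPReference:
    """Named curated reference gene sets plus the gene universe they live in."""

    sets: dict[str, tuple[str, ...]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.sets = {k: tuple(v) for k, v in self.sets.items()}
        self.universe = frozenset(self.universe)
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"reference set {name!r} is empty")
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(f"reference set {name!r} has genes outside the universe: "
                                 f"{sorted(extra)[:5]}")

    @classmethod
    def from_gmt(cls, sets: dict, universe=None) -> "MPReference":
        sets = {k: tuple(v) for k, v in sets.items()}
        if universe is None:
            universe = set().union(*map(set, sets.values()))
        return cls(sets, frozenset(universe))


def mp_similarity(gp: GPCluster, mp_name: str, mp_genes,
                  scores: ScoreMatrix) -> tuple[float, float]:
    """(mean Jaccard, score correlation) between one GP and one MP.

    The Jaccard term averages over the GP's constituent programs' top-gene
    lists; the correlation term is the Pearson correlation of per-cell
    scores, which must both be present as columns of ``scores``.
    """
    mean_j = float(np.mean([jaccard_index(m.genes, mp_genes) for m in gp.members]))
    for col in (gp.gp_id, mp_name):
        if col not in scores.raw.columns:
            raise ValueError(f"score matrix lacks a column for {col!r}")
    a = scores.raw[gp.gp_id].to_numpy()
    b = scores.raw[mp_name].to_numpy()
    if a.size == 0:
        raise ValueError("no common cells between GP and MP scores")
    if np.std(a) == 0 or np.std(b) == 0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(a, b)[0, 1])
    return mean_j, corr


@dataclass
class PermutationThresholds:
    jaccard: float
    correlation: float
    n_perm: int
    confidence: float
    null_jaccard: np.ndarray
    null_correlation: np.ndarray


def permutation_thresholds(gps: list[GPCluster], mp_ref: MPReference,
                           expr: ExpressionMatrix, mp_scores: ScoreMatrix,
                           n_perm: int = 100, confidence: float = 0.999,
                           seed: int = 0, n_background: int = 200,
                           n_bins: int = 30) -> PermutationThresholds:
    """Pooled permutation null thresholds for the two similarity statistics.

    Each permutation replaces every constituent program's gene list by a
    uniform random same-size draw from the scored matrix's gene universe.
    Permuted mean-Jaccard values are pooled over (GP, MP, permutation);
    for the correlation null, each permuted GP is scored (random set of the
    signature's size, ``n_background`` matched background sets) and
    correlated with every MP's per-cell score. Thresholds are the
    ``confidence`` quantile of each pooled null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = np.asarray(expr.gene_ids, dtype=object)
    largest = max(max(len(m.genes) for m in gp.members) for gp in gps)
    largest = max(largest, max(len(gp.signature) for gp in gps))
    if universe.size < largest:
        raise ValueError(f"gene universe ({universe.size}) smaller than the largest "
                         f"program ({largest})")
    rng = np.random.default_rng(seed)
    null_j, null_c = [], []
    for perm in range(n_perm):
        for gp in gps:
            perm_lists = [rng.choice(universe, size=len(m.genes), replace=False)
                          for m in gp.members]
            for mp_name, mp_genes in mp_ref.sets.items():
                mj = float(np.mean([jaccard_index(pl, mp_genes) for pl in perm_lists]))
                null_j.append(mj)
            sig_perm = rng.choice(universe, size=len(set(gp.signature)), replace=False)
            bg_seed = int(rng.integers(2**31))
            bg = build_background_sets(expr, sig_perm, n_sets=n_background,
                                       n_bins=n_bins, seed=bg_seed)
            sc = score_cells(expr, sig_perm, bg, program_id="perm")
            for mp_name in mp_ref.sets:
                b = mp_scores.raw[mp_name].to_numpy()
                if np.std(sc.raw) == 0 or np.std(b) == 0:
                    null_c.append(0.0)
                else:
                    null_c.append(float(np.corrcoef(sc.raw, b)[0, 1]))
    null_j = np.asarray(null_j)
    null_c = np.asarray(null_c)
    return PermutationThresholds(
        jaccard=float(np.quantile(null_j, confidence)),
        correlation=float(np.quantile(null_c, confidence)),
        n_perm=n_perm, confidence=confidence,
        null_jaccard=null_j, null_correlation=null_c)


def hypergeom_overlap(set_a, set_b, universe_size: int) -> float:
    """Upper-tail hypergeometric p-value of the observed overlap.

    Probability of drawing at least ``|a n b|`` members of ``set_a`` when
    ``|set_b|`` genes are drawn without replacement from a universe of
    ``universe_size``.
    """
    a, b = set(set_a), set(set_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("set larger than the universe")
    if len(a | b) > universe_size:
        raise ValueError("union of sets exceeds the universe")
    k = len(a & b)
    return float(scipy.stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def annotate_gps(gps: list[GPCluster], mp_ref: MPReference,
                 expr: ExpressionMatrix, scores: ScoreMatrix,
                 n_perm: int = 100, confidence: float = 0.999, seed: int = 0,
                 universe_size: int | None = None,
                 n_background: int = 200, n_bins: int = 30) -> pd.DataFrame:
    """Full GP-vs-MP similarity table with permutation and hypergeometric tests.

    ``scores`` must hold per-cell score columns for every GP (by gp_id) and
    every MP (by name). The hypergeometric universe defaults to the genes of
    the scored matrix. Returns one row per (GP, MP) with mean_jaccard,
    mean_correlation, permutation thresholds, a significance flag (both
    statistics above threshold) and BH-adjusted hypergeometric q-values.
    """
    if universe_size is None:
        universe_size = expr.n_genes
    thr = permutation_thresholds(gps, mp_ref, expr, scores, n_perm=n_perm,
                                 confidence=confidence, seed=seed,
                                 n_background=n_background, n_bins=n_bins)
    rows = []
    for gp in gps:
        for mp_name, mp_genes in mp_ref.sets.items():
            mj, mc = mp_similarity(gp, mp_name, mp_genes, scores)
            hp = hypergeom_overlap(gp.signature, mp_genes, universe_size)
            rows.append(dict(gp_id=gp.gp_id, mp_id=mp_name, mean_jaccard=mj,
                             mean_correlation=mc,
                             jaccard_threshold=thr.jaccard,
                             correlation_threshold=thr.correlation,
                             significant=bool(mj > thr.jaccard and mc > thr.correlation),
                             hypergeom_p=hp))
    out = pd.DataFrame(rows)
    out["fdr_q"] = fdr_adjust(out["hypergeom_p"].to_numpy())
    return out


def detection_frequency(counts: CountMatrix, mode: str = "per_line") -> pd.Series:
    """Per-gene detection frequency.

    ``"per_line"`` (default): fraction of sample lines in which the gene is
    detected (count > 0 in at least one cell); a frequency of 1 means the
    gene is seen in every line. ``"per_cell"``: fraction of cells with a
    nonzero count.
    """
    if mode == "per_line":
        lines = pd.unique(pd.Series(counts.line_labels))
        det = np.zeros(counts.n_genes)
        for line in lines:
            m = counts.line_labels == line
            det += (counts.values[:, m] > 0).any(axis=1)
        freq = det / len(lines)
    elif mode == "per_cell":
        freq = (counts.values > 0).mean(axis=1)
    else:
        raise ValueError(f"unknown detection mode {mode!r}")
    return pd.Series(freq, index=pd.Index(counts.gene_ids, name="gene"))


def read_sasp_table(path) -> pd.DataFrame:
    """Read a long-format SASP TSV (gene, condition, log2fc) into genes x conditions."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "condition", "log2fc"}
    if not need <= set(df.columns):
        raise ValueError(f"SASP table must have columns {sorted(need)}")
    return df.pivot_table(index="gene", columns="condition", values="log2fc",
                          aggfunc="first")


def select_representative_genes(gp_genes, sasp: pd.DataFrame,
                                detection: pd.Series,
                                companion_sets: dict | None = None,
                                log2fc_min: float = 2.0,
                                detection_required: float = 1.0) -> pd.DataFrame:
    """Two-route representative-gene selection for a secreted program.

    Route A (SASP): GP genes with secretion log2 fold-change strictly above
    ``log2fc_min`` in at least one senescence condition AND detection
    frequency equal to ``detection_required``. Route B (companion): GP genes
    shared with any companion gene set. Returns one row per selected gene
    with boolean route columns.
    """
    gp_genes = [str(g) for g in gp_genes]
    companion_sets = companion_sets or {}
    companion_union: set[str] = set()
    for genes in companion_sets.values():
        companion_union |= set(map(str, genes))

    rows = []
    for g in gp_genes:
        route_a = False
        if g in sasp.index:
            fc = sasp.loc[g]
            route_a = bool(np.nanmax(fc.to_numpy(dtype=float)) > log2fc_min) \
                if not fc.isna().all() else False
            det = float(detection.get(g, 0.0))
            route_a = route_a and np.isclose(det, detection_required)
        route_b = g in companion_union
        if route_a or route_b:
            rows.append(dict(gene=g, sasp_route=route_a, companion_route=route_b))
    return pd.DataFrame(rows, columns=["gene", "sasp_route", "companion_route"])
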