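"""Robust-program filtering, redundancy-removing selection, and UPGMA clustering.

From the pool of per-line NMF programs (top-50 gene lists across several
ranks), robust programs are those that (1) recur across factorization ranks
within their own line - at least 70% overlap (35 of 50 genes) with a
program of a different K - and (2) are shared across lines - at least 20%
overlap (10 of 50 genes) with a program of another line. Robust programs
are then (3) ranked by their similarity to other lines' programs and
scanned in decreasing order; a program is dropped when an already selected
program from the same line overlaps it by more than 20% (strictly more than
10 of 50 genes). The selected programs are clustered by UPGMA (average
linkage) on Jaccard distance, and each cluster's signature is the set of
genes present in at least 40% of its member programs.

When programs are shorter than the nominal 50 genes (small matrices), all
gene-count thresholds rescale as ceil(fraction x shorter list length).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .nmf import Program, ProgramCollection

__all__ = [
    "ConsensusParams",
    "GPCluster",
    "jaccard_index",
    "overlap_count",
    "robust_filter",
    "rank_programs",
    "greedy_select",
    "cluster_programs",
    "program_linkage",
    "signature_genes",
    "linkage_to_newick",
]

NOMINAL_PROGRAM_SIZE = 50


@dataclass(frozen=True)
class ConsensusParams:
    """Thresholds of the three robustness criteria and the clustering cut.

    ``intra_line_overlap_min`` / ``inter_line_overlap_min`` are inclusive
    shared-gene counts for nominal 50-gene programs (35 = 70%, 10 = 20%);
    ``redundancy_overlap_max`` is the strict exclusion bound of the greedy
    scan (overlap > 10 of 50 excludes, exactly 10 does not). The matching
    fractions are used to rescale thresholds for shorter programs.
    ``ranking`` selects the criterion-3 statistic: ``"max"`` (maximum
    Jaccard to any other-line program) or ``"mean_of_max"`` (mean over
    other lines of the per-line maximum).
    """

    intra_line_overlap_min: int = 35
    inter_line_overlap_min: int = 10
    redundancy_overlap_max: int = 10
    intra_fraction: float = 0.70
    inter_fraction: float = 0.20
    redundancy_fraction: float = 0.20
    signature_min_fraction: float = 0.40
    n_clusters: int = 7
    ranking: str = "max"
    require_inter_line: bool = True

    def __post_init__(self) -> None:
        if min(self.intra_line_overlap_min, self.inter_line_overlap_min,
               self.redundancy_overlap_max) <= 0:
            raise ValueError("overlap thresholds must be positive")
        if not 0.0 < self.signature_min_fraction <= 1.0:
            raise ValueError("signature_min_fraction must lie in (0, 1]")
        if self.ranking not in ("max", "mean_of_max"):
            raise ValueError(f"unknown ranking statistic {self.ranking!r}")


@dataclass
class GPCluster:
    """One consensus gene program: a cluster of robust NMF programs."""

    gp_id: str
    members: list[Program]
    signature: list[str]
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("GPCluster requires at least one member program")
        union = set().union(*(m.gene_set for m in self.members))
        if not set(self.signature) <= union:
            raise ValueError("signature genes must come from member programs")


def jaccard_index(a, b) -> float:
    """|a n b| / |a u b| for two nonempty gene sets."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("jaccard_index requires nonempty sets")
    return len(a & b) / len(a | b)


def overlap_count(a, b) -> int:
    return len(set(a) & set(b))


def _scaled(threshold: int, fraction: float, len_a: int, len_b: int) -> int:
    """Gene-count threshold, rescaled when either list is short of 50."""
    shorter = min(len_a, len_b)
    if shorter >= NOMINAL_PROGRAM_SIZE:
        return threshold
    return math.ceil(fraction * shorter)


def robust_filter(collection: ProgramCollection,
                  params: ConsensusParams = ConsensusParams()) -> ProgramCollection:
    """Retain programs passing both the cross-rank and cross-line criteria.

    Criterion 1: at least ``intra_line_overlap_min`` shared genes with some
    program of a *different* K in the same line. Criterion 2: at least
    ``inter_line_overlap_min`` shared genes with some program of another
    line. Both are evaluated against the full input collection. A
    single-line collection triggers a warning; criterion 2 then removes
    everything unless ``require_inter_line=False``.
    """
    programs = list(collection)
    lines = collection.lines
    if len(lines) < 2 and params.require_inter_line and programs:
        warnings.warn("collection spans a single line; the inter-line criterion "
                      "will retain nothing (set require_inter_line=False to skip it)",
                      stacklevel=2)
    kept = []
    for p in programs:
        c1 = any(
            overlap_count(p.genes, q.genes)
            >= _scaled(params.intra_line_overlap_min, params.intra_fraction,
                       len(p.genes), len(q.genes))
            for q in programs
            if q.line_id == p.line_id and q.k != p.k
        )
        if not c1:
            continue
        if params.require_inter_line:
            c2 = any(
                overlap_count(p.genes, q.genes)
                >= _scaled(params.inter_line_overlap_min, params.inter_fraction,
                           len(p.genes), len(q.genes))
                for q in programs if q.line_id != p.line_id
            )
            if not c2:
                continue
        kept.append(p)
    return ProgramCollection(kept)


def rank_programs(collection: ProgramCollection,
                  params: ConsensusParams = ConsensusParams()) -> list[Program]:
    """Order programs by decreasing similarity to other lines' programs.

    The per-program statistic is the maximum Jaccard index to any program of
    another line (or, with ``ranking="mean_of_max"``, the mean over other
    lines of the per-line maximum). Ties are broken by (line, k, component)
    ascending for determinism.
    """
    programs = list(collection)

    def stat(p: Program) -> float:
        per_line: dict[str, float] = {}
        for q in programs:
            if q.line_id == p.line_id:
                continue
            j = jaccard_index(p.genes, q.genes)
            per_line[q.line_id] = max(per_line.get(q.line_id, 0.0), j)
        if not per_line:
            return 0.0
        if params.ranking == "max":
            return max(per_line.values())
        return float(np.mean(list(per_line.values())))

    return sorted(programs, key=lambda p: (-stat(p), p.key))


def greedy_select(robust: ProgramCollection,
                  params: ConsensusParams = ConsensusParams()) -> ProgramCollection:
    """Scan ranked programs, dropping same-line redundancy.

    A program is selected unless a previously selected program from the
    same line shares strictly more than ``redundancy_overlap_max`` genes
    with it. Output preserves selection order.
    """
    selected: list[Program] = []
    for p in rank_programs(robust, params):
        redundant = any(
            overlap_count(p.genes, s.genes)
            > _scaled(params.redundancy_overlap_max, params.redundancy_fraction,
                      len(p.genes), len(s.genes))
            for s in selected if s.line_id == p.line_id
        )
        if not redundant:
            selected.append(p)
    return ProgramCollection(selected)


def program_linkage(selected: ProgramCollection) -> np.ndarray:
    """UPGMA linkage matrix on 1 - Jaccard distances between programs."""
    programs = list(selected)
    if len(programs) < 2:
        raise ValueError("need at least 2 programs to cluster")
    n = len(programs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = 1.0 - jaccard_index(programs[i].genes, programs[j].genes)
            dist[i, j] = dist[j, i] = d
    return sch.linkage(ssd.squareform(dist, checks=False), method="average")


def signature_genes(members: list[Program], min_fraction: float = 0.40) -> list[str]:
    """Genes present in at least ``min_fraction`` of the member programs.

    The threshold is inclusive: with 5 members and min_fraction 0.40, a gene
    in 2 members qualifies. Output is ordered by occurrence count
    descending, then gene id ascending.
    """
    if not members:
        raise ValueError("signature_genes requires a nonempty member list")
    counts: dict[str, int] = {}
    for m in members:
        for g in m.gene_set:
            counts[g] = counts.get(g, 0) + 1
    need = math.ceil(min_fraction * len(members))
    hits = [(g, c) for g, c in counts.items() if c >= need]
    hits.sort(key=lambda gc: (-gc[1], gc[0]))
    return [g for g, _ in hits]


def cluster_programs(selected: ProgramCollection,
                     params: ConsensusParams = ConsensusParams()) -> list[GPCluster]:
    """UPGMA-cluster the selected programs and extract cluster signatures.

    The average-linkage tree on Jaccard distance is cut into
    ``params.n_clusters`` flat clusters. Clusters are numbered GP1, GP2, ...
    in order of first appearance in the selection order. Raises
    ``ValueError`` when more clusters are requested than programs exist.
    """
    programs = list(selected)
    if params.n_clusters > len(programs):
        raise ValueError(f"n_clusters={params.n_clusters} exceeds program count {len(programs)}")
    if len(programs) == 1:
        only = programs[0]
        return [GPCluster("GP1", [only], signature_genes([only], params.signature_min_fraction))]
    Z = program_linkage(selected)
    labels = sch.fcluster(Z, t=params.n_clusters, criterion="maxclust")
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order) + 1
    clusters = []
    for lab, gp_num in order.items():
        members = [p for p, l in zip(programs, labels) if l == lab]
        sig = signature_genes(members, params.signature_min_fraction)
        clusters.append(GPCluster(f"GP{gp_num}", members, sig))
    return clusters


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string (for inspection)."""
    n = len(leaf_names)

    def node(i: int) -> tuple[str, float]:
        if i < n:
            return leaf_names[i], 0.0
        a, b, height, _ = Z[i - n]
        sa, ha = node(int(a))
        sb, hb = node(int(b))
        return (f"({sa}:{height - ha:.6g},{sb}:{height - hb:.6g})", height)

    s, _ = node(n + len(Z) - 1)
    return s + ";"
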