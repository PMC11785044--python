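"""Per-cell gene-program scoring against expression-matched background sets.

For each program, 1,000 background gene sets of the same size are drawn so
that their expression-level profile matches the program's: genes are binned
into equal-frequency bins by mean expression, and each program gene is
replaced by a random gene from its own bin. Each cell's program activity is
the average mean-centered expression of the program genes; the p-value is
the proportion of background sets whose average centered expression in that
cell strictly exceeds the program's, with a +1 pseudocount in numerator and
denominator so p is never zero. The score is -log10(p), linearly rescaled
to [0, 1] across cells per program.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import ExpressionMatrix

__all__ = [
    "BackgroundSets",
    "ProgramScores",
    "ScoreMatrix",
    "build_background_sets",
    "score_cells",
    "score_programs",
]


@dataclass
class BackgroundSets:
    """Expression-matched background draws for one query gene set.

    ``sets`` is an ``(n_sets, set_size)`` integer array of gene indices
    into the expression matrix the sets were built on; ``bin_of`` maps each
    gene index to its expression bin.
    """

    query_genes: tuple[str, ...]
    sets: np.ndarray
    bin_of: np.ndarray
    n_bins: int
    seed: int
    gene_ids: np.ndarray

    @property
    def n_sets(self) -> int:
        return self.sets.shape[0]

    def set_gene_ids(self, i: int) -> list[str]:
        return [str(g) for g in self.gene_ids[self.sets[i]]]


def build_background_sets(expr: ExpressionMatrix, gene_set, n_sets: int = 1000,
                          n_bins: int = 30, seed: int = 0) -> BackgroundSets:
    """Draw ``n_sets`` background gene sets matched to ``gene_set``.

    Genes are ranked by mean expression across cells (ties broken by gene
    id) and split into ``n_bins`` equal-frequency bins. Each background set
    replaces every query gene with a draw from that gene's bin; draws within
    one set and one bin are without replacement, so each set's per-bin gene
    histogram equals the query's.
    """
    gene_ids = np.asarray(expr.gene_ids, dtype=object)
    pos = {g: i for i, g in enumerate(gene_ids)}
    query = [str(g) for g in gene_set]
    missing = [g for g in query if g not in pos]
    if missing:
        raise ValueError(f"query genes absent from expression matrix: {missing}")
    if len(set(query)) != len(query):
        raise ValueError("query gene set contains duplicates")

    means = expr.values.mean(axis=1)
    order = np.lexsort((gene_ids.astype(str), means))
    bin_of = np.empty(len(gene_ids), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b

    q_idx = np.array([pos[g] for g in query])
    bin_members = {b: np.flatnonzero(bin_of == b) for b in np.unique(bin_of[q_idx])}
    for b, members in bin_members.items():
        if members.size < 2:
            raise ValueError(f"expression bin {b} holds a query gene but only "
                             f"{members.size} gene(s); use fewer bins")

    rng = np.random.default_rng(seed)
    sets = np.empty((n_sets, len(query)), dtype=int)
    # positions of query genes grouped by bin, to fill each draw in place
    by_bin = {b: np.flatnonzero(bin_of[q_idx] == b) for b in bin_members}
    for s in range(n_sets):
        for b, slots in by_bin.items():
            members = bin_members[b]
            replace = slots.size > members.size
            sets[s, slots] = rng.choice(members, size=slots.size, replace=replace)
    return BackgroundSets(query_genes=tuple(query), sets=sets, bin_of=bin_of,
                          n_bins=n_bins, seed=seed, gene_ids=gene_ids)


@dataclass
class ProgramScores:
    """Per-cell scores of one program: p-value, -log10(p), rescaled [0,1]."""

    program_id: str
    cell_ids: np.ndarray
    p: np.ndarray
    raw: np.ndarray
    rescaled: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cell_id": self.cell_ids, "program_id": self.program_id,
                             "p": self.p, "raw": self.raw, "rescaled": self.rescaled})


def _rescale(raw: np.ndarray, groups: np.ndarray | None = None) -> np.ndarray:
    def mm(x):
        lo, hi = x.min(), x.max()
        if hi == lo:
            return np.zeros_like(x)
        return (x - lo) / (hi - lo)

    if groups is None:
        return mm(raw)
    out = np.empty_like(raw)
    for g in np.unique(groups):
        m = groups == g
        out[m] = mm(raw[m])
    return out


def score_cells(expr: ExpressionMatrix, gene_set, backgrounds: BackgroundSets,
                program_id: str = "program", rescale: str = "global") -> ProgramScores:
    """Score every cell of ``expr`` for one gene program.

    Activity is measured on mean-centered expression (per gene, across the
    scored cells). Per cell, p = (1 + number of background sets with higher
    mean centered expression) / (1 + n_sets); ties count as not exceeding.
    ``rescale`` is ``"global"`` (one [0,1] scale across all cells, the
    default since scores are compared across lines) or ``"per_line"``.
    """
    query = tuple(str(g) for g in gene_set)
    if query != backgrounds.query_genes:
        raise ValueError("backgrounds were built for a different query set")
    if not np.array_equal(np.asarray(expr.gene_ids, dtype=object), backgrounds.gene_ids):
        raise ValueError("backgrounds were built on a different gene universe")
    if rescale not in ("global", "per_line"):
        raise ValueError(f"unknown rescale mode {rescale!r}")

    centered = expr.values - expr.values.mean(axis=1, keepdims=True)
    pos = {g: i for i, g in enumerate(expr.gene_ids)}
    q_idx = np.array([pos[g] for g in query])
    query_mean = centered[q_idx].mean(axis=0)              # (cells,)

    n_sets = backgrounds.n_sets
    exceed = np.zeros(expr.n_cells, dtype=int)
    for s in range(n_sets):
        bg_mean = centered[backgrounds.sets[s]].mean(axis=0)
        exceed += bg_mean > query_mean
    p = (1.0 + exceed) / (1.0 + n_sets)
    raw = -np.log10(p)
    groups = expr.line_labels if rescale == "per_line" else None
    return ProgramScores(program_id, expr.cell_ids, p, raw, _rescale(raw, groups))


@dataclass
class ScoreMatrix:
    """Scores of several programs over a common cell set."""

    cell_ids: np.ndarray
    line_labels: np.ndarray
    p: pd.DataFrame          # cells x programs
    raw: pd.DataFrame
    rescaled: pd.DataFrame

    @property
    def program_ids(self) -> list[str]:
        return list(self.rescaled.columns)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for prog in self.program_ids:
            frames.append(pd.DataFrame({
                "cell_id": self.cell_ids, "program_id": prog,
                "p": self.p[prog].to_numpy(), "raw": self.raw[prog].to_numpy(),
                "rescaled": self.rescaled[prog].to_numpy()}))
        return pd.concat(frames, ignore_index=True)


def score_programs(expr: ExpressionMatrix, gene_sets: dict, n_sets: int = 1000,
                   n_bins: int = 30, seed: int = 0,
                   rescale: str = "global") -> ScoreMatrix:
    """Score a collection of programs; one seeded background build each.

    The per-program background seed is derived from ``seed`` and the gene
    set's content, so two identical gene sets (under different names)
    receive identical backgrounds and identical scores.
    """
    import hashlib

    cols_p, cols_raw, cols_res = {}, {}, {}
    for name, genes in gene_sets.items():
        blob = f"{seed}:" + ",".join(sorted(map(str, genes)))
        set_seed = int.from_bytes(hashlib.sha256(blob.encode()).digest()[:4],
                                  "big") % (2**31)
        bg = build_background_sets(expr, genes, n_sets=n_sets, n_bins=n_bins,
                                   seed=set_seed)
        sc = score_cells(expr, genes, bg, program_id=name, rescale=rescale)
        cols_p[name], cols_raw[name], cols_res[name] = sc.p, sc.raw, sc.rescaled
    idx = pd.Index(expr.cell_ids, name="cell_id")
    return ScoreMatrix(expr.cell_ids, expr.line_labels,
                       pd.DataFrame(cols_p, index=idx),
                       pd.DataFrame(cols_raw, index=idx),
                       pd.DataFrame(cols_res, index=idx))
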