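"""Cell/gene quality control and normalization for UMI count matrices.

The QC stage retains cells by five rules evaluated on the raw counts:
total UMIs, detected-gene count (lower and upper bound), library complexity
("novelty score", log10 detected genes / log10 total UMIs) and mitochondrial
count fraction; genes are then kept when expressed in strictly more than a
configured fraction of the retained cells. Normalization scales each cell to
one million total counts and applies log2(x + 1); for 3' UMI data this
counts-per-million transform is the appropriate reading of log2(TPM+1)
because UMI counts carry no gene-length term. The NMF substrate is the
per-gene mean-centered matrix with negative entries clipped to zero.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "QCParams",
    "QCReport",
    "ExpressionMatrix",
    "CenteredNonneg",
    "qc_filter",
    "normalize_log_tpm",
    "center_and_clip",
]


@dataclass
class CountMatrix:
    """Raw genes x cells nonnegative integer counts with cell line labels.

    Attributes
    ----------
    values
        ``(n_genes, n_cells)`` array of nonnegative integers.
    gene_ids, cell_ids
        Unique identifiers for rows and columns.
    line_labels
        Sample-line label per cell (one organoid line per cell).
    mito_mask
        Boolean flag per gene marking mitochondrial genes.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    line_labels: np.ndarray
    mito_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.line_labels = np.asarray(self.line_labels, dtype=object)
        self.mito_mask = np.asarray(self.mito_mask, dtype=bool)
        n_genes, n_cells = self.values.shape
        if self.gene_ids.shape != (n_genes,):
            raise ValueError("gene_ids length does not match matrix rows")
        if self.cell_ids.shape != (n_cells,) or self.line_labels.shape != (n_cells,):
            raise ValueError("cell_ids/line_labels length does not match matrix columns")
        if self.mito_mask.shape != (n_genes,):
            raise ValueError("mito_mask length does not match matrix rows")
        if self.values.size and self.values.min() < 0:
            raise ValueError("count matrix contains negative entries")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene ids are not unique")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell ids are not unique")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_idx: np.ndarray | None = None,
               cell_idx: np.ndarray | None = None) -> "CountMatrix":
        g = np.arange(self.n_genes) if gene_idx is None else np.asarray(gene_idx)
        c = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        return CountMatrix(
            values=self.values[np.ix_(g, c)],
            gene_ids=self.gene_ids[g],
            cell_ids=self.cell_ids[c],
            line_labels=self.line_labels[c],
            mito_mask=self.mito_mask[g],
        )


@dataclass(frozen=True)
class QCParams:
    """Cell/gene filtering thresholds.

    Boundary conventions follow the printed rules: UMI and detected-gene
    bounds are inclusive ("at least"), the novelty and mitochondrial rules
    are strict. ``novelty_mode`` selects how "log10 genes per UMI" is read:
    ``"ratio_of_logs"`` (the community novelty score,
    log10(genes)/log10(UMIs)) or the literal ``"log_of_ratio"``
    (log10(genes/UMIs), always negative, kept only as an explicit switch).
    """

    min_umis: int = 500
    min_genes: int = 200
    max_genes: int = 8000
    min_log10_genes_per_umi: float = 0.80
    max_mito_fraction: float = 0.10
    min_cell_fraction_per_gene: float = 0.001
    novelty_mode: str = "ratio_of_logs"

    def __post_init__(self) -> None:
        if self.min_genes > self.max_genes:
            raise ValueError("min_genes must not exceed max_genes")
        for name in ("max_mito_fraction", "min_cell_fraction_per_gene"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.novelty_mode not in ("ratio_of_logs", "log_of_ratio"):
            raise ValueError(f"unknown novelty_mode: {self.novelty_mode!r}")


@dataclass
class QCReport:
    """Per-rule removal counts from one :func:`qc_filter` run.

    ``cells_removed_by_rule`` counts, for each rule independently, the input
    cells that fail it (a cell can fail several rules). ``empty`` is set when
    no cell survives, so callers can branch without a crash.
    """

    cells_in: int
    cells_out: int
    genes_in: int
    genes_out: int
    cells_removed_by_rule: dict[str, int]
    genes_removed: int
    empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": rule, "cells_removed": n}
                for rule, n in self.cells_removed_by_rule.items()]
        rows.append({"rule": "gene_min_cell_fraction", "cells_removed": self.genes_removed})
        return pd.DataFrame(rows)


@dataclass
class ExpressionMatrix:
    """log2(CPM + 1) expression, genes x cells, with provenance labels."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    line_labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.line_labels = np.asarray(self.line_labels, dtype=object)
        if self.values.size and self.values.min() < 0:
            raise ValueError("expression values must be nonnegative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cell_idx: np.ndarray) -> "ExpressionMatrix":
        c = np.asarray(cell_idx)
        return ExpressionMatrix(self.values[:, c], self.gene_ids,
                                self.cell_ids[c], self.line_labels[c])


@dataclass
class CenteredNonneg:
    """Per-gene mean-centered expression with negatives clipped to zero.

    ``gene_means`` stores the subtracted means so the centering is
    reversible up to the clipped negatives.
    """

    values: np.ndarray
    gene_means: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    line_labels: np.ndarray

    def __post_init__(self) -> None:
        if self.values.size and self.values.min() < 0:
            raise ValueError("clipped matrix must be nonnegative")


def _cell_metrics(counts: CountMatrix, novelty_mode: str):
    umis = counts.values.sum(axis=0)
    detected = (counts.values > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        if novelty_mode == "ratio_of_logs":
            novelty = np.where(umis > 1, np.log10(np.maximum(detected, 1)) /
                               np.where(umis > 1, np.log10(umis), 1.0), 0.0)
        else:
            novelty = np.where(umis > 0, np.log10(np.maximum(detected, 1e-300) / np.maximum(umis, 1)), -np.inf)
        mito_frac = np.where(umis > 0,
                             counts.values[counts.mito_mask].sum(axis=0) / np.maximum(umis, 1),
                             0.0)
    return umis, detected, novelty, mito_frac


def qc_filter(counts: CountMatrix, params: QCParams = QCParams()) -> tuple[CountMatrix, QCReport]:
    """Apply the five cell rules, then the gene detection-fraction rule.

    Cells are retained when total UMIs >= ``min_umis``, detected genes lie in
    ``[min_genes, max_genes]``, the novelty score exceeds
    ``min_log10_genes_per_umi`` (strict) and the mitochondrial count fraction
    is below ``max_mito_fraction`` (strict). Genes are retained when expressed
    (count > 0) in strictly more than ``min_cell_fraction_per_gene`` of the
    retained cells; the gene rule is evaluated on the post-cell-filter matrix.

    Returns the filtered matrix and a :class:`QCReport`. An empty result is a
    valid outcome, signalled by ``report.empty``.
    """
    umis, detected, novelty, mito_frac = _cell_metrics(counts, params.novelty_mode)

    rules = {
        "min_umis": umis >= params.min_umis,
        "min_genes": detected >= params.min_genes,
        "max_genes": detected <= params.max_genes,
        "novelty": novelty > params.min_log10_genes_per_umi,
        "mito_fraction": mito_frac < params.max_mito_fraction,
    }
    keep_cells = np.ones(counts.n_cells, dtype=bool)
    removed = {}
    for name, passed in rules.items():
        removed[name] = int((~passed).sum())
        keep_cells &= passed

    cell_idx = np.flatnonzero(keep_cells)
    filtered = counts.subset(cell_idx=cell_idx)

    if filtered.n_cells == 0:
        report = QCReport(counts.n_cells, 0, counts.n_genes, 0, removed,
                          genes_removed=counts.n_genes, empty=True)
        return filtered.subset(gene_idx=np.array([], dtype=int)), report

    expressed_frac = (filtered.values > 0).sum(axis=1) / filtered.n_cells
    keep_genes = expressed_frac > params.min_cell_fraction_per_gene
    gene_idx = np.flatnonzero(keep_genes)
    out = filtered.subset(gene_idx=gene_idx)

    report = QCReport(
        cells_in=counts.n_cells, cells_out=out.n_cells,
        genes_in=counts.n_genes, genes_out=out.n_genes,
        cells_removed_by_rule=removed,
        genes_removed=int((~keep_genes).sum()),
        empty=out.n_cells == 0 or out.n_genes == 0,
    )
    return out, report


def normalize_log_tpm(counts: CountMatrix) -> ExpressionMatrix:
    """Scale each cell to one million total counts, then apply log2(x + 1).

    Raises ``ValueError`` naming the first offending cell if any cell has a
    zero total (normalization is undefined there).
    """
    totals = counts.values.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(f"cell {counts.cell_ids[zero[0]]!r} has zero total counts; "
                         "remove empty cells (qc_filter) before normalizing")
    cpm = counts.values / totals[np.newaxis, :] * 1e6
    return ExpressionMatrix(np.log2(cpm + 1.0), counts.gene_ids,
                            counts.cell_ids, counts.line_labels)


def center_and_clip(expr: ExpressionMatrix) -> CenteredNonneg:
    """Subtract each gene's mean across cells and set negative values to zero."""
    if expr.values.size == 0:
        raise ValueError("cannot center an empty expression matrix")
    means = expr.values.mean(axis=1)
    centered = expr.values - means[:, np.newaxis]
    return CenteredNonneg(np.maximum(centered, 0.0), means, expr.gene_ids,
                          expr.cell_ids, expr.line_labels)
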