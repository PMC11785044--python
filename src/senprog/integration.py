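"""Cross-dataset joint PCA for program-state visualization.

Datasets (e.g. organoid lines, patient tumors, patient-derived organoids)
are restricted to their shared genes, mean-centered per gene *within each
dataset* (removing dataset-level offsets), and concatenated. PCA is run on
the top 4,500 genes by pre-centering mean expression, and the PC pair best
correlated with two program scores of interest (|r| > 0.35, two-sided) is
chosen for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .preprocessing import ExpressionMatrix

__all__ = [
    "JointDataset",
    "PCSelection",
    "PCPairResult",
    "joint_center",
    "joint_pca",
    "select_pc_pair",
]


@dataclass
class JointDataset:
    """Shared-gene concatenation of per-dataset centered matrices."""

    values: np.ndarray             # genes x cells, centered per dataset per gene
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    dataset_labels: np.ndarray
    dataset_gene_means: dict[str, np.ndarray]
    pre_center_gene_means: np.ndarray   # combined mean expression before centering


@dataclass
class PCSelection:
    """PCA scores over the joint cells."""

    scores: np.ndarray             # cells x n_pcs
    cell_ids: np.ndarray
    dataset_labels: np.ndarray
    explained_variance_ratio: np.ndarray
    genes_used: np.ndarray
    all_genes_used: bool           # True when fewer than top_genes were available


@dataclass
class PCPairResult:
    """Outcome of the correlation-driven PC pair search."""

    chosen: tuple[int, int] | None     # (PC for program 1, PC for program 2), 0-based
    correlations: pd.DataFrame         # PCs x programs, Pearson r
    qualifies: bool


def joint_center(datasets: list[ExpressionMatrix],
                 labels: list[str] | None = None) -> JointDataset:
    """Restrict to shared genes, center per gene within each dataset, concatenate."""
    if len(datasets) < 2:
        raise ValueError("joint_center needs at least 2 datasets")
    if labels is None:
        labels = [f"dataset{i}" for i in range(len(datasets))]
    if len(labels) != len(datasets):
        raise ValueError("one label per dataset required")
    shared = set(datasets[0].gene_ids)
    for d in datasets[1:]:
        shared &= set(d.gene_ids)
    if not shared:
        raise ValueError("datasets share no genes")
    shared_genes = np.array(sorted(shared), dtype=object)

    blocks, pre_means, means_by_ds, cells, ds_labels = [], [], {}, [], []
    for d, lab in zip(datasets, labels):
        pos = {g: i for i, g in enumerate(d.gene_ids)}
        idx = np.array([pos[g] for g in shared_genes])
        sub = d.values[idx]
        m = sub.mean(axis=1)
        means_by_ds[lab] = m
        blocks.append(sub - m[:, np.newaxis])
        pre_means.append(sub)
        cells.append(np.array([f"{lab}:{c}" for c in d.cell_ids], dtype=object))
        ds_labels.append(np.full(d.n_cells, lab, dtype=object))
    combined_pre = np.concatenate(pre_means, axis=1)
    return JointDataset(
        values=np.concatenate(blocks, axis=1),
        gene_ids=shared_genes,
        cell_ids=np.concatenate(cells),
        dataset_labels=np.concatenate(ds_labels),
        dataset_gene_means=means_by_ds,
        pre_center_gene_means=combined_pre.mean(axis=1),
    )


def joint_pca(joint: JointDataset, top_genes: int = 4500, n_pcs: int = 10) -> PCSelection:
    """PCA scores of the joint dataset on its top genes.

    The gene subset is the ``top_genes`` genes with the highest mean
    pre-centering expression across the combined cells (all genes when the
    matrix has fewer, flagged in the result).
    """
    n_genes, n_cells = joint.values.shape
    n_take = min(top_genes, n_genes)
    order = np.argsort(-joint.pre_center_gene_means, kind="stable")[:n_take]
    sub = joint.values[np.sort(order)]
    rank_cap = min(sub.shape[0], n_cells)
    if n_pcs > rank_cap:
        raise ValueError(f"n_pcs={n_pcs} exceeds the attainable rank {rank_cap}")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(sub.T)
    return PCSelection(scores=scores, cell_ids=joint.cell_ids,
                       dataset_labels=joint.dataset_labels,
                       explained_variance_ratio=pca.explained_variance_ratio_,
                       genes_used=joint.gene_ids[np.sort(order)],
                       all_genes_used=n_take == n_genes)


def select_pc_pair(pcs: PCSelection, program_scores: pd.DataFrame,
                   r_threshold: float = 0.35, top_pcs: int = 10) -> PCPairResult:
    """Choose the PC pair best correlated with two program scores.

    ``program_scores`` is a cells x 2 frame (index = joint cell ids,
    columns = the two programs of interest). Among ordered pairs of
    distinct PCs from the first ``top_pcs``, the pair maximizing the
    minimum |Pearson r| - PC_i with program 1, PC_j with program 2 - is
    chosen, provided each |r| strictly exceeds ``r_threshold``. When no
    pair qualifies the result carries the full correlation table and
    ``qualifies=False`` instead of raising.
    """
    if program_scores.shape[1] != 2:
        raise ValueError("exactly two program score columns are required")
    common = pd.Index(pcs.cell_ids).intersection(program_scores.index)
    if common.empty:
        raise ValueError("no shared cells between PC scores and program scores")
    cell_pos = {c: i for i, c in enumerate(pcs.cell_ids)}
    rows = [cell_pos[c] for c in common]
    S = pcs.scores[rows]
    P = program_scores.loc[common].to_numpy(dtype=float)

    n_pcs = min(top_pcs, S.shape[1])
    corr = np.zeros((n_pcs, 2))
    for i in range(n_pcs):
        for j in range(2):
            a, b = S[:, i], P[:, j]
            corr[i, j] = 0.0 if (a.std() == 0 or b.std() == 0) else np.corrcoef(a, b)[0, 1]
    table = pd.DataFrame(corr, index=[f"PC{i + 1}" for i in range(n_pcs)],
                         columns=list(program_scores.columns))

    best, best_val = None, -np.inf
    for i, j in permutations(range(n_pcs), 2):
        val = min(abs(corr[i, 0]), abs(corr[j, 1]))
        if val > r_threshold and val > best_val:
            best, best_val = (i, j), val
    return PCPairResult(chosen=best, correlations=table, qualifies=best is not None)
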