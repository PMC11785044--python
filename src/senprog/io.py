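"""Readers and writers for the plain-text formats used across the pipeline.

Count matrices travel as MatrixMarket (MTX) triplets with ``genes.tsv`` /
``barcodes.tsv`` sidecars; gene sets as GMT; tabular results as TSV.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_counts_mtx",
    "write_counts_mtx",
]


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read a GMT file into ``{set_name: [gene, ...]}`` (description dropped)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need name, description, genes): {line[:80]!r}")
            name = fields[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name in GMT: {name!r}")
            sets[name] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | os.PathLike,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_counts_mtx(values: np.ndarray, gene_ids: Sequence[str], cell_ids: Sequence[str],
                     line_labels: Sequence[str], mito_mask: Sequence[bool],
                     prefix: str | os.PathLike) -> None:
    """Write a genes x cells integer matrix as ``<prefix>.mtx`` plus sidecars.

    Sidecars are ``<prefix>.genes.tsv`` (gene_id, is_mito) and
    ``<prefix>.barcodes.tsv`` (cell_id, line).
    """
    prefix = os.fspath(prefix)
    sparse = scipy.sparse.coo_matrix(np.asarray(values))
    scipy.io.mmwrite(prefix + ".mtx", sparse, field="integer")
    pd.DataFrame({"gene_id": list(gene_ids), "is_mito": np.asarray(mito_mask, dtype=int)}).to_csv(
        prefix + ".genes.tsv", sep="\t", index=False)
    pd.DataFrame({"cell_id": list(cell_ids), "line": list(line_labels)}).to_csv(
        prefix + ".barcodes.tsv", sep="\t", index=False)


def read_counts_mtx(prefix: str | os.PathLike):
    """Read a matrix written by :func:`write_counts_mtx`.

    Returns a :class:`senprog.preprocessing.CountMatrix`. If the genes sidecar
    lacks an ``is_mito`` column, mitochondrial genes are flagged by the
    conventional ``mt-`` name prefix (case-insensitive).
    """
    from .preprocessing import CountMatrix

    prefix = os.fspath(prefix)
    values = np.asarray(scipy.io.mmread(prefix + ".mtx").todense())
    genes = pd.read_csv(prefix + ".genes.tsv", sep="\t")
    cells = pd.read_csv(prefix + ".barcodes.tsv", sep="\t")
    if "is_mito" in genes.columns:
        mito = genes["is_mito"].astype(bool).to_numpy()
    else:
        mito = genes["gene_id"].str.lower().str.startswith("mt-").to_numpy()
    return CountMatrix(
        values=values.astype(np.int64),
        gene_ids=genes["gene_id"].astype(str).to_numpy(),
        cell_ids=cells["cell_id"].astype(str).to_numpy(),
        line_labels=cells["line"].astype(str).to_numpy(),
        mito_mask=mito,
    )
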