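"""Per-line NMF over a rank range and extraction of top-gene programs.

Each sample line's centered-nonnegative matrix is factorized at every rank
K in a configured range (default 6-9). Each of the K basis components is
summarized as a "program": its top 50 genes ranked by basis coefficient.
Running K = 6..9 therefore yields 6 + 7 + 8 + 9 = 30 programs per line, the
raw material for the consensus filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF as _SkNMF
from sklearn.exceptions import ConvergenceWarning

from .preprocessing import CenteredNonneg

__all__ = [
    "NMFResult",
    "Program",
    "ProgramCollection",
    "run_nmf",
    "extract_programs",
    "run_nmf_range",
    "nmf_seed",
]

DEFAULT_KS: tuple[int, ...] = (6, 7, 8, 9)
DEFAULT_TOP_N = 50


@dataclass
class NMFResult:
    """One nonnegative factorization: values ~ basis @ loadings."""

    basis: np.ndarray       # genes x k
    loadings: np.ndarray    # k x cells
    k: int
    seed: int
    n_iter: int
    reconstruction_error: float
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    line_id: str


@dataclass(frozen=True)
class Program:
    """Top-gene summary of one NMF component.

    ``genes`` holds the ``top_n`` highest-coefficient genes in strictly
    non-increasing coefficient order (coefficient ties broken by gene id
    ascending); ``short`` flags matrices with fewer than ``top_n`` genes.
    """

    line_id: str
    k: int
    component_index: int
    genes: tuple[str, ...]
    coefficients: tuple[float, ...]
    short: bool = False

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.line_id, self.k, self.component_index)

    @property
    def name(self) -> str:
        return f"{self.line_id}_k{self.k}_c{self.component_index}"

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


class ProgramCollection:
    """Ordered collection of :class:`Program` indexed by (line, k, component)."""

    def __init__(self, programs=()):
        self._programs: list[Program] = []
        self._index: dict[tuple[str, int, int], Program] = {}
        for p in programs:
            self.add(p)

    def add(self, program: Program) -> None:
        if program.key in self._index:
            raise ValueError(f"duplicate program index {program.key}")
        self._index[program.key] = program
        self._programs.append(program)

    def extend(self, programs) -> None:
        for p in programs:
            self.add(p)

    def __len__(self) -> int:
        return len(self._programs)

    def __iter__(self):
        return iter(self._programs)

    def __getitem__(self, key):
        if isinstance(key, int):
            return self._programs[key]
        return self._index[key]

    def __contains__(self, key) -> bool:
        return key in self._index

    @property
    def lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self._programs:
            seen.setdefault(p.line_id, None)
        return list(seen)

    def by_line(self, line_id: str) -> list[Program]:
        return [p for p in self._programs if p.line_id == line_id]

    def to_gmt_dict(self) -> dict[str, list[str]]:
        return {p.name: list(p.genes) for p in self._programs}


def run_nmf(matrix: CenteredNonneg, k: int, seed: int = 0,
            max_iter: int = 500, tol: float = 1e-4,
            line_id: str | None = None) -> NMFResult:
    """Factorize a centered-nonnegative matrix at rank ``k``.

    Coordinate-descent Frobenius NMF with NNDSVD initialization (zeros
    perturbed by small seeded random values), so runs are deterministic
    given ``seed``. Stops when the relative error improvement drops below
    ``tol`` or after ``max_iter`` iterations.
    """
    X = matrix.values
    n_genes, n_cells = X.shape
    if not 1 <= k <= min(n_genes, n_cells):
        raise ValueError(f"rank k={k} outside valid range [1, {min(n_genes, n_cells)}]")
    model = _SkNMF(n_components=k, init="nndsvdar", solver="cd",
                   beta_loss="frobenius", tol=tol, max_iter=max_iter,
                   random_state=int(seed) % (2**32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(X)
    H = model.components_
    err = float(np.linalg.norm(X - W @ H))
    if line_id is None:
        line_id = str(matrix.line_labels[0]) if len(matrix.line_labels) else "line"
    return NMFResult(basis=W, loadings=H, k=k, seed=seed, n_iter=model.n_iter_,
                     reconstruction_error=err, gene_ids=matrix.gene_ids,
                     cell_ids=matrix.cell_ids, line_id=line_id)


def extract_programs(result: NMFResult, top_n: int = DEFAULT_TOP_N) -> list[Program]:
    """Summarize each component by its ``top_n`` basis genes.

    Genes are ranked by basis coefficient descending; coefficient ties are
    broken by gene id ascending so extraction is deterministic. A matrix
    with fewer than ``top_n`` genes yields shorter programs flagged
    ``short=True``.
    """
    n_genes = result.basis.shape[0]
    n_take = min(top_n, n_genes)
    gene_ids = np.asarray(result.gene_ids, dtype=object)
    programs = []
    # lexsort: last key is primary => sort by -coef, then gene id ascending
    id_rank = np.argsort(np.argsort(gene_ids.astype(str)))
    for c in range(result.k):
        coef = result.basis[:, c]
        order = np.lexsort((id_rank, -coef))[:n_take]
        programs.append(Program(
            line_id=result.line_id, k=result.k, component_index=c,
            genes=tuple(str(g) for g in gene_ids[order]),
            coefficients=tuple(float(v) for v in coef[order]),
            short=n_take < top_n,
        ))
    return programs


def nmf_seed(base_seed: int, line_id: str, k: int) -> int:
    """Deterministic per-(line, k) seed derived from a base seed."""
    ss = np.random.SeedSequence([int(base_seed) % (2**31), k,
                                 abs(hash(line_id)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_nmf_range(matrix: CenteredNonneg, ks=DEFAULT_KS, seed: int = 0,
                  top_n: int = DEFAULT_TOP_N, line_id: str | None = None,
                  max_iter: int = 500, tol: float = 1e-4) -> ProgramCollection:
    """Run NMF at every rank in ``ks`` on one line's matrix.

    Returns ``sum(ks)`` programs (e.g. 30 for K = 6..9), each tagged with
    its rank and component index. Each (line, k) run uses its own seed
    derived from ``seed``.
    """
    if line_id is None:
        line_id = str(matrix.line_labels[0]) if len(matrix.line_labels) else "line"
    collection = ProgramCollection()
    for k in ks:
        res = run_nmf(matrix, k, seed=nmf_seed(seed, line_id, k),
                      max_iter=max_iter, tol=tol, line_id=line_id)
        collection.extend(extract_programs(res, top_n=top_n))
    return collection
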