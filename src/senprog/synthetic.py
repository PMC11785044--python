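"""Synthetic multi-line scRNA-seq counts and drug-screen plates with ground truth.

The count generator emulates the structure of a multi-line organoid
single-cell experiment: several sample "lines" of UMI counts with lognormal
baseline gene means shared across lines, per-cell library-size variation,
negative-binomial sampling noise, a mitochondrial gene subset (named with
the conventional ``mt-`` prefix), and planted co-expression programs active
in a subset of cells. Programs can be present in all lines (robust, expected
to survive the consensus filter), restricted to one line (expected to be
removed by the inter-line criterion), or rank-unstable (split into two
half-programs active in complementary cell subsets, so a single merged
component appears only at some factorization ranks).

Gene-level noise follows a two-population dispersion model: a stable
majority of genes with low negative-binomial overdispersion and a
highly-variable minority (``hvg_fraction``) with large overdispersion,
mirroring the long dispersion tail of real UMI data. Planted program genes
are drawn from the stable pool. This reproduces, at panel scale, the one
statistical property the downstream consensus filter relies on: gene lists
of noise-driven NMF components concentrate on the highly-variable
population and are therefore nearly disjoint from program gene lists. In
genome-wide data that disjointness comes for free from the size of the
genome (two random 50-gene lists share ~0 genes); on a small panel it must
be built into the noise structure, since two random 50-of-200 lists would
share ~12 genes and swamp any overlap-based criterion.

The plate generator produces ATP-viability screening tables whose drug wells
follow the median-effect (Hill-type) dose-response fa = (D/Dm)^m / (1 + (D/Dm)^m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ProgramSpec",
    "SimConfig",
    "GroundTruth",
    "generate_counts",
    "PlateLayout",
    "DoseResponse",
    "generate_plate",
]


@dataclass(frozen=True)
class ProgramSpec:
    """One planted co-expression program.

    ``effect_multiplier`` scales the expected counts of program genes in
    active cells. ``lines_present`` lists line indices carrying the program
    (``None`` = all lines). ``rank_stable=False`` plants the program as two
    half-strength gene subsets active in complementary halves of the active
    cells, so it is detected as one component only at some ranks.
    """

    gene_count: int = 50
    active_cell_fraction: float = 0.3
    effect_multiplier: float = 8.0
    lines_present: tuple[int, ...] | None = None
    rank_stable: bool = True
    name: str | None = None

    def __post_init__(self) -> None:
        if self.gene_count < 10:
            raise ValueError(f"ProgramSpec.gene_count must be >= 10, got {self.gene_count}")
        if not 0.0 < self.active_cell_fraction <= 1.0:
            raise ValueError("ProgramSpec.active_cell_fraction must lie in (0, 1]")
        if self.effect_multiplier <= 1.0:
            raise ValueError("ProgramSpec.effect_multiplier must exceed 1")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the count simulation.

    ``library_size_range`` is the (uniform) range of expected per-cell totals
    for a cell with no active program; active cells exceed it by the planted
    fold-change. ``dispersion`` is the negative-binomial overdispersion alpha
    in var = mu + alpha mu^2 for the stable gene majority; alpha = 0 falls
    back to Poisson sampling. A fraction ``hvg_fraction`` of genes is
    highly variable with overdispersion ``hvg_dispersion``; program genes
    are never drawn from that population (see module docstring).
    """

    n_lines: int = 3
    cells_per_line: int = 300
    n_genes: int = 200
    mito_gene_fraction: float = 0.05
    baseline_logmean_mu: float = 0.0
    baseline_logmean_sigma: float = 0.5
    library_size_range: tuple[float, float] = (2000.0, 6000.0)
    dispersion: float = 0.1
    hvg_fraction: float = 0.45
    hvg_dispersion: float = 3.0
    programs: tuple[ProgramSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise ValueError("SimConfig.n_lines must be positive")
        if self.cells_per_line < 1:
            raise ValueError("SimConfig.cells_per_line must be positive")
        if self.n_genes < 50:
            raise ValueError(f"SimConfig.n_genes must be >= 50, got {self.n_genes}")
        if not 0.0 <= self.mito_gene_fraction <= 1.0:
            raise ValueError("SimConfig.mito_gene_fraction must lie in [0, 1]")
        if self.baseline_logmean_sigma < 0:
            raise ValueError("SimConfig.baseline_logmean_sigma must be nonnegative")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("SimConfig.library_size_range must satisfy 0 < low <= high")
        if self.dispersion < 0:
            raise ValueError("SimConfig.dispersion must be nonnegative")
        if not 0.0 <= self.hvg_fraction < 1.0:
            raise ValueError("SimConfig.hvg_fraction must lie in [0, 1)")
        if self.hvg_dispersion < 0:
            raise ValueError("SimConfig.hvg_dispersion must be nonnegative")
        object.__setattr__(self, "programs", tuple(self.programs))
        for spec in self.programs:
            if spec.lines_present is not None:
                bad = [i for i in spec.lines_present if not 0 <= i < self.n_lines]
                if bad:
                    raise ValueError(f"ProgramSpec.lines_present indices out of range: {bad}")
        n_mito = round(self.mito_gene_fraction * self.n_genes)
        n_hvg = round(self.hvg_fraction * self.n_genes)
        pool = self.n_genes - n_mito - n_hvg
        need = sum(s.gene_count for s in self.programs)
        # program gene sets are drawn disjointly from the stable non-mito pool
        if need > pool:
            raise ValueError("SimConfig.programs request more genes than the "
                             f"stable non-mito gene pool holds ({need} > {pool})")


@dataclass
class GroundTruth:
    """Planted structure of one simulated dataset.

    ``program_genes`` maps program name -> gene id list; ``activity`` maps
    program name -> boolean per-cell activity vector (over all cells, all
    lines); ``lines_present`` maps program name -> line labels carrying it;
    ``hvg_genes`` lists the highly-variable (non-program) gene population.
    """

    program_genes: dict[str, list[str]]
    activity: dict[str, np.ndarray]
    lines_present: dict[str, list[str]]
    hvg_genes: list[str] = field(default_factory=list)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray,
               dispersion: np.ndarray) -> np.ndarray:
    """Negative-binomial draw with per-gene overdispersion (rows of ``mean``).

    Genes with dispersion 0 are sampled as Poisson (the NB limit).
    """
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=float)[:, None], mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    pois = dispersion == 0.0
    if pois.any():
        out[pois] = rng.poisson(mean[pois])
    if (~pois).any():
        size = 1.0 / dispersion[~pois]   # NB "number of successes" parameter
        p = size / (size + mean[~pois])
        out[~pois] = rng.negative_binomial(size, p)
    return out


def generate_counts(config: SimConfig):
    """Simulate a multi-line UMI count matrix with planted programs.

    Returns ``(CountMatrix, GroundTruth)``. Deterministic given
    ``config.seed``: the same configuration yields byte-identical output.
    """
    from .preprocessing import CountMatrix

    rng = np.random.default_rng(config.seed)
    n_mito = round(config.mito_gene_fraction * config.n_genes)
    gene_ids = np.array(
        [f"mt-{i + 1}" for i in range(n_mito)]
        + [f"g{i + 1:04d}" for i in range(config.n_genes - n_mito)],
        dtype=object)
    mito_mask = np.zeros(config.n_genes, dtype=bool)
    mito_mask[:n_mito] = True

    baseline = rng.lognormal(config.baseline_logmean_mu, config.baseline_logmean_sigma,
                             size=config.n_genes)

    # two-population dispersion: stable majority + highly-variable minority;
    # program genes come from the stable non-mito pool (see module docstring)
    dispersion = np.full(config.n_genes, float(config.dispersion))
    non_mito = np.flatnonzero(~mito_mask)
    n_hvg = round(config.hvg_fraction * config.n_genes)
    hvg_idx = np.sort(rng.choice(non_mito, size=min(n_hvg, non_mito.size), replace=False))
    dispersion[hvg_idx] = config.hvg_dispersion
    pool = rng.permutation(np.setdiff1d(non_mito, hvg_idx))

    line_labels_unique = [f"line{i}" for i in range(config.n_lines)]
    n_cells = config.n_lines * config.cells_per_line
    cell_line_idx = np.repeat(np.arange(config.n_lines), config.cells_per_line)
    line_labels = np.array([line_labels_unique[i] for i in cell_line_idx], dtype=object)
    cell_ids = np.array([f"{line_labels[j]}_c{(j % config.cells_per_line) + 1:04d}"
                         for j in range(n_cells)], dtype=object)

    # assign disjoint gene blocks and per-line activity masks
    program_genes: dict[str, list[str]] = {}
    activity: dict[str, np.ndarray] = {}
    lines_present: dict[str, list[str]] = {}
    gene_idx_of: dict[str, np.ndarray] = {}
    offset = 0
    for p, spec in enumerate(config.programs):
        name = spec.name or f"program{p + 1}"
        idx = np.sort(pool[offset:offset + spec.gene_count])
        offset += spec.gene_count
        gene_idx_of[name] = idx
        program_genes[name] = [str(g) for g in gene_ids[idx]]
        present = (tuple(range(config.n_lines)) if spec.lines_present is None
                   else tuple(spec.lines_present))
        lines_present[name] = [line_labels_unique[i] for i in present]
        act = np.zeros(n_cells, dtype=bool)
        for li in present:
            cells = np.flatnonzero(cell_line_idx == li)
            n_active = round(spec.active_cell_fraction * cells.size)
            act[rng.choice(cells, size=n_active, replace=False)] = True
        activity[name] = act

    # expected counts: baseline weights scaled to the library size of an
    # inactive cell, then multiplied by the planted fold-changes
    lib = rng.uniform(*config.library_size_range, size=n_cells)
    weights = baseline / baseline.sum()
    mu = np.outer(weights, lib)
    for p, spec in enumerate(config.programs):
        name = spec.name or f"program{p + 1}"
        idx = gene_idx_of[name]
        act = np.flatnonzero(activity[name])
        if act.size == 0:
            continue
        if spec.rank_stable:
            mu[np.ix_(idx, act)] *= spec.effect_multiplier
        else:
            half = spec.gene_count // 2
            g1, g2 = idx[:half], idx[half:]
            c1 = act[: act.size // 2]
            c2 = act[act.size // 2:]
            weak = np.sqrt(spec.effect_multiplier)
            mu[np.ix_(g1, c1)] *= spec.effect_multiplier
            mu[np.ix_(g2, c1)] *= weak
            mu[np.ix_(g2, c2)] *= spec.effect_multiplier
            mu[np.ix_(g1, c2)] *= weak

    values = _nb_sample(rng, mu, dispersion)

    counts = CountMatrix(values=values, gene_ids=gene_ids, cell_ids=cell_ids,
                         line_labels=line_labels, mito_mask=mito_mask)
    truth = GroundTruth(program_genes=program_genes, activity=activity,
                        lines_present=lines_present,
                        hvg_genes=[str(g) for g in gene_ids[hvg_idx]])
    return counts, truth


# ---------------------------------------------------------------------------
# drug-screen plates


@dataclass(frozen=True)
class DoseResponse:
    """Median-effect parameters of one drug: fa = (D/Dm)^m / (1 + (D/Dm)^m).

    ``max_effect`` caps the attainable affected fraction (1.0 = full kill at
    saturating dose).
    """

    m: float
    dm: float
    max_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.dm <= 0:
            raise ValueError("DoseResponse.dm must be positive")
        if self.m <= 0:
            raise ValueError("DoseResponse.m must be positive")
        if not 0 < self.max_effect <= 1:
            raise ValueError("DoseResponse.max_effect must lie in (0, 1]")

    def fa(self, dose: float | np.ndarray) -> np.ndarray:
        dose = np.asarray(dose, dtype=float)
        r = (dose / self.dm) ** self.m
        return self.max_effect * r / (1.0 + r)


@dataclass(frozen=True)
class PlateLayout:
    """Well layout of one screening plate.

    ``doses`` maps drug name -> dose series; every (drug, dose) gets
    ``n_replicates`` wells, plus ``n_control_wells`` DMSO wells. Organoid
    sizes are recorded on day 4 (pre-treatment) and day 6; untreated
    organoids grow by ``control_growth`` over that window and drug effect
    suppresses growth proportionally to the affected fraction.
    """

    doses: dict[str, tuple[float, ...]]
    dose_unit: str = "uM"
    n_replicates: int = 3
    n_control_wells: int = 6
    baseline_signal: float = 1.0e6
    baseline_size: float = 100.0
    control_growth: float = 2.0

    def __post_init__(self) -> None:
        if self.n_control_wells < 3:
            raise ValueError("PlateLayout.n_control_wells must be >= 3 (DMSO controls)")
        for drug, ds in self.doses.items():
            if any(d <= 0 for d in ds):
                raise ValueError(f"non-positive dose for drug {drug!r}")


def generate_plate(layout: PlateLayout, dose_response: dict[str, DoseResponse],
                   noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Simulate one screening plate as a tidy table.

    Columns: well, drug, dose, unit, replicate, is_control, atp_signal,
    size_day4, size_day6. DMSO control wells carry the baseline signal;
    drug wells are scaled by ``1 - fa(dose)`` under each drug's
    median-effect curve. Gaussian noise with standard deviation
    ``noise_sd`` (as a fraction of baseline) is added to ATP signals.
    Deterministic given ``seed``.
    """
    missing = [d for d in layout.doses if d not in dose_response]
    if missing:
        raise ValueError(f"no dose-response parameters for drugs: {missing}")
    rng = np.random.default_rng(seed)
    rows = []
    w = 0
    for i in range(layout.n_control_wells):
        w += 1
        rows.append(dict(well=f"W{w:03d}", drug="DMSO", dose=0.0, unit=layout.dose_unit,
                         replicate=i + 1, is_control=True, viability=1.0))
    for drug, ds in layout.doses.items():
        curve = dose_response[drug]
        for dose in ds:
            for rep in range(layout.n_replicates):
                w += 1
                rows.append(dict(well=f"W{w:03d}", drug=drug, dose=float(dose),
                                 unit=layout.dose_unit, replicate=rep + 1,
                                 is_control=False,
                                 viability=float(1.0 - curve.fa(dose))))
    plate = pd.DataFrame(rows)
    noise = rng.normal(0.0, noise_sd * layout.baseline_signal, size=len(plate)) \
        if noise_sd > 0 else np.zeros(len(plate))
    plate["atp_signal"] = plate["viability"] * layout.baseline_signal + noise
    plate["size_day4"] = layout.baseline_size
    growth = 1.0 + (layout.control_growth - 1.0) * plate["viability"]
    plate["size_day6"] = layout.baseline_size * growth
    return plate.drop(columns="viability")
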