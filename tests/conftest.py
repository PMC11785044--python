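import numpy as np
import pytest

from senprog import (ProgramSpec, QCParams, SimConfig, generate_counts,
                     normalize_log_tpm, qc_filter)
from senprog.nmf import Program

# QC thresholds scaled to the 200-gene synthetic panel (the genome-wide
# defaults assume thousands of detectable genes per cell)
PANEL_QC = QCParams(min_umis=500, min_genes=50, max_genes=8000,
                    min_log10_genes_per_umi=0.5, max_mito_fraction=0.25,
                    min_cell_fraction_per_gene=0.001)


@pytest.fixture(scope="session")
def sim_bundle():
    """3-line dataset with one shared and one line-specific planted program."""
    cfg = SimConfig(seed=7, programs=(
        ProgramSpec(name="shared"),
        ProgramSpec(lines_present=(0,), name="specific"),
    ))
    counts, truth = generate_counts(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def sim_expr(sim_bundle):
    _, counts, _ = sim_bundle
    filtered, _ = qc_filter(counts, PANEL_QC)
    return normalize_log_tpm(filtered)


@pytest.fixture(scope="session")
def null_expr():
    """Single-line, program-free expression matrix for null-calibration tests."""
    cfg = SimConfig(n_lines=1, cells_per_line=500, n_genes=200, seed=3, programs=())
    counts, _ = generate_counts(cfg)
    return normalize_log_tpm(counts)


def make_program(line_id, k, comp, genes):
    """Program with synthetic strictly-decreasing coefficients."""
    genes = tuple(genes)
    return Program(line_id=line_id, k=k, component_index=comp, genes=genes,
                   coefficients=tuple(float(len(genes) - i) for i in range(len(genes))))
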