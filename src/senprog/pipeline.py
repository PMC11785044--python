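"""Stage orchestration: one config, deterministic seeds, manifest output.

``run_pipeline`` executes simulate (optional) -> qc -> normalize -> nmf ->
consensus -> score -> annotate -> integrate, writing each stage's outputs
and a manifest (stage list, effective parameters, derived seeds, output
checksums) to the output directory. All stage defaults are the analysis'
standard parameterization (QC 500/200/8000/0.80/10%/0.001; K = 6-9; top-50;
35/10/>10; 40% signature; 1,000 background sets; 100 permutations; 99.9%
confidence; 4,500 PCA genes; |r| > 0.35). Reruns with an identical config
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from . import io as sio
from .annotation import MPReference, annotate_gps
from .consensus import (ConsensusParams, cluster_programs, greedy_select,
                        jaccard_index, linkage_to_newick, program_linkage,
                        robust_filter)
from .integration import joint_center, joint_pca, select_pc_pair
from .nmf import ProgramCollection, run_nmf_range
from .preprocessing import QCParams, center_and_clip, normalize_log_tpm, qc_filter
from .scoring import score_programs
from .synthetic import ProgramSpec, SimConfig, generate_counts

logger = logging.getLogger("senprog")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "config_from_dict"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _from_dict(cls, data: dict, path: str):
    import typing

    known = {f.name: f for f in fields(cls)}
    hints = typing.get_type_hints(cls)
    unknown = [k for k in data if k not in known]
    if unknown:
        raise ValueError(f"unknown config key {path}{unknown[0]!r}")
    kwargs = {}
    for k, v in data.items():
        ftype = hints.get(k)
        if dataclasses.is_dataclass(ftype) and isinstance(v, dict):
            kwargs[k] = _from_dict(ftype, v, f"{path}{k}.")
        else:
            kwargs[k] = v
    return cls(**kwargs)


@dataclass
class SimulateBlock:
    enabled: bool = True
    n_lines: int = 3
    cells_per_line: int = 300
    n_genes: int = 200
    mito_gene_fraction: float = 0.05
    baseline_logmean_mu: float = 0.0
    baseline_logmean_sigma: float = 0.5
    library_size_min: float = 2000.0
    library_size_max: float = 6000.0
    dispersion: float = 0.1
    hvg_fraction: float = 0.45
    hvg_dispersion: float = 3.0
    programs: list = field(default_factory=lambda: [
        dict(gene_count=50, active_cell_fraction=0.3, effect_multiplier=8.0)])


@dataclass
class QCBlock:
    min_umis: int = 500
    min_genes: int = 200
    max_genes: int = 8000
    min_log10_genes_per_umi: float = 0.80
    max_mito_fraction: float = 0.10
    min_cell_fraction_per_gene: float = 0.001
    novelty_mode: str = "ratio_of_logs"


@dataclass
class NMFBlock:
    ks: list = field(default_factory=lambda: [6, 7, 8, 9])
    top_n: int = 50
    max_iter: int = 500
    tol: float = 1e-4


@dataclass
class ConsensusBlock:
    intra_line_overlap_min: int = 35
    inter_line_overlap_min: int = 10
    redundancy_overlap_max: int = 10
    signature_min_fraction: float = 0.40
    n_clusters: int = 7
    ranking: str = "max"


@dataclass
class ScoreBlock:
    n_background: int = 1000
    n_bins: int = 30
    rescale: str = "global"


@dataclass
class AnnotateBlock:
    enabled: bool = True
    mps_gmt: str | None = None       # defaults to the simulated ground truth
    n_perm: int = 100
    confidence: float = 0.999
    n_background: int = 200


@dataclass
class IntegrateBlock:
    enabled: bool = True
    top_genes: int = 4500
    n_pcs: int = 10
    r_threshold: float = 0.35


@dataclass
class PipelineConfig:
    outdir: str = "senprog_out"
    seed: int = 0
    input_prefix: str | None = None   # MTX prefix to load instead of simulating
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    qc: QCBlock = field(default_factory=QCBlock)
    nmf: NMFBlock = field(default_factory=NMFBlock)
    consensus: ConsensusBlock = field(default_factory=ConsensusBlock)
    score: ScoreBlock = field(default_factory=ScoreBlock)
    annotate: AnnotateBlock = field(default_factory=AnnotateBlock)
    integrate: IntegrateBlock = field(default_factory=IntegrateBlock)


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a config from a plain mapping, rejecting unknown keys by name."""
    return _from_dict(PipelineConfig, data, "")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _log_stage(stage: str, seed: int, params) -> None:
    blob = json.dumps(dataclasses.asdict(params), sort_keys=True, default=str)
    phash = hashlib.sha256(blob.encode()).hexdigest()[:12]
    logger.info("stage=%s seed=%d params=%s", stage, seed, phash)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written as manifest.json)."""
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}

    def record(stage: str, seed: int, files: list[str], **extra) -> None:
        manifest["stages"].append({"stage": stage, "seed": seed, **extra})
        for f in files:
            manifest["outputs"][os.path.basename(f)] = _sha256(f)

    # ---- simulate / load -------------------------------------------------
    if config.input_prefix is not None:
        counts = sio.read_counts_mtx(config.input_prefix)
        truth = None
        record("load", 0, [], input_prefix=str(config.input_prefix))
    else:
        sim = config.simulate
        if not sim.enabled:
            raise ValueError("stage 'simulate' disabled but no input_prefix given")
        seed = stage_seed(config.seed, "simulate")
        specs = tuple(ProgramSpec(**p) for p in sim.programs)
        sc = SimConfig(
            n_lines=sim.n_lines, cells_per_line=sim.cells_per_line,
            n_genes=sim.n_genes, mito_gene_fraction=sim.mito_gene_fraction,
            baseline_logmean_mu=sim.baseline_logmean_mu,
            baseline_logmean_sigma=sim.baseline_logmean_sigma,
            library_size_range=(sim.library_size_min, sim.library_size_max),
            dispersion=sim.dispersion, hvg_fraction=sim.hvg_fraction,
            hvg_dispersion=sim.hvg_dispersion, programs=specs, seed=seed)
        counts, truth = generate_counts(sc)
        _log_stage("simulate", seed, sim)
        prefix = os.path.join(out, "counts")
        sio.write_counts_mtx(counts.values, counts.gene_ids, counts.cell_ids,
                             counts.line_labels, counts.mito_mask, prefix)
        sio.write_gmt(truth.program_genes, os.path.join(out, "ground_truth.gmt"))
        pd.DataFrame({"cell_id": counts.cell_ids,
                      **{name: act.astype(int) for name, act in truth.activity.items()}
                      }).to_csv(os.path.join(out, "ground_truth_cells.tsv"),
                                sep="\t", index=False)
        record("simulate", seed,
               [prefix + ext for ext in (".mtx", ".genes.tsv", ".barcodes.tsv")]
               + [os.path.join(out, "ground_truth.gmt"),
                  os.path.join(out, "ground_truth_cells.tsv")])

    # ---- qc --------------------------------------------------------------
    qc_params = QCParams(**dataclasses.asdict(config.qc))
    filtered, report = qc_filter(counts, qc_params)
    _log_stage("qc", 0, config.qc)
    report.to_frame().to_csv(os.path.join(out, "qc_report.tsv"), sep="\t", index=False)
    fprefix = os.path.join(out, "filtered")
    sio.write_counts_mtx(filtered.values, filtered.gene_ids, filtered.cell_ids,
                         filtered.line_labels, filtered.mito_mask, fprefix)
    record("qc", 0, [os.path.join(out, "qc_report.tsv")]
           + [fprefix + ext for ext in (".mtx", ".genes.tsv", ".barcodes.tsv")],
           cells_out=report.cells_out, genes_out=report.genes_out)
    if report.empty:
        manifest["status"] = "empty_after_qc"
        _write_manifest(manifest, out)
        return manifest

    # ---- normalize -------------------------------------------------------
    expr = normalize_log_tpm(filtered)
    record("normalize", 0, [])

    # ---- nmf (per line) --------------------------------------------------
    nmf_seed_base = stage_seed(config.seed, "nmf")
    _log_stage("nmf", nmf_seed_base, config.nmf)
    all_programs = ProgramCollection()
    lines = list(dict.fromkeys(expr.line_labels))
    for line in lines:
        idx = np.flatnonzero(expr.line_labels == line)
        line_expr = expr.subset_cells(idx)
        centered = center_and_clip(line_expr)
        coll = run_nmf_range(centered, ks=tuple(config.nmf.ks), seed=nmf_seed_base,
                             top_n=config.nmf.top_n, line_id=str(line),
                             max_iter=config.nmf.max_iter, tol=config.nmf.tol)
        all_programs.extend(coll)
    sio.write_gmt(all_programs.to_gmt_dict(), os.path.join(out, "programs.gmt"))
    coef_rows = [dict(program=p.name, gene=g, coefficient=c)
                 for p in all_programs for g, c in zip(p.genes, p.coefficients)]
    pd.DataFrame(coef_rows).to_csv(os.path.join(out, "program_coefficients.tsv"),
                                   sep="\t", index=False, float_format="%.8g")
    record("nmf", nmf_seed_base,
           [os.path.join(out, "programs.gmt"),
            os.path.join(out, "program_coefficients.tsv")],
           n_programs=len(all_programs))

    # ---- consensus -------------------------------------------------------
    cp = ConsensusParams(
        intra_line_overlap_min=config.consensus.intra_line_overlap_min,
        inter_line_overlap_min=config.consensus.inter_line_overlap_min,
        redundancy_overlap_max=config.consensus.redundancy_overlap_max,
        signature_min_fraction=config.consensus.signature_min_fraction,
        n_clusters=config.consensus.n_clusters,
        ranking=config.consensus.ranking)
    _log_stage("consensus", 0, config.consensus)
    robust = robust_filter(all_programs, cp)
    selected = greedy_select(robust, cp)
    n_clusters = min(cp.n_clusters, max(len(selected), 1))
    cp_eff = dataclasses.replace(cp, n_clusters=n_clusters)
    gps = cluster_programs(selected, cp_eff) if len(selected) else []

    sio.write_gmt({p.name: list(p.genes) for p in robust},
                  os.path.join(out, "robust_programs.gmt"))
    sio.write_gmt({p.name: list(p.genes) for p in selected},
                  os.path.join(out, "selected_programs.gmt"))
    sio.write_gmt({gp.gp_id: gp.signature for gp in gps},
                  os.path.join(out, "gp_clusters.gmt"),
                  descriptions={gp.gp_id: ",".join(m.name for m in gp.members)
                                for gp in gps})
    files = [os.path.join(out, f) for f in
             ("robust_programs.gmt", "selected_programs.gmt", "gp_clusters.gmt")]
    if len(selected) >= 2:
        progs = list(selected)
        sim_mat = pd.DataFrame(
            [[jaccard_index(a.genes, b.genes) for b in progs] for a in progs],
            index=[p.name for p in progs], columns=[p.name for p in progs])
        sim_mat.to_csv(os.path.join(out, "similarity_matrix.tsv"), sep="\t",
                       float_format="%.6g")
        Z = program_linkage(selected)
        with open(os.path.join(out, "merge_tree.nwk"), "w") as fh:
            fh.write(linkage_to_newick(Z, [p.name for p in progs]) + "\n")
        files += [os.path.join(out, "similarity_matrix.tsv"),
                  os.path.join(out, "merge_tree.nwk")]
    record("consensus", 0, files, n_robust=len(robust), n_selected=len(selected),
           n_gps=len(gps))

    # ---- score -----------------------------------------------------------
    score_seed = stage_seed(config.seed, "score")
    _log_stage("score", score_seed, config.score)
    gene_sets: dict[str, list[str]] = {gp.gp_id: list(gp.signature) for gp in gps
                                       if gp.signature}
    mp_sets: dict[str, list[str]] = {}
    if config.annotate.enabled:
        if config.annotate.mps_gmt is not None:
            mp_sets = sio.read_gmt(config.annotate.mps_gmt)
        elif truth is not None:
            mp_sets = {f"MP_{k}": v for k, v in truth.program_genes.items()}
    expr_universe = set(map(str, expr.gene_ids))
    mp_sets = {k: [g for g in v if g in expr_universe] for k, v in mp_sets.items()}
    mp_sets = {k: v for k, v in mp_sets.items() if v}
    scores = None
    if gene_sets or mp_sets:
        scores = score_programs(expr, {**gene_sets, **mp_sets},
                                n_sets=config.score.n_background,
                                n_bins=config.score.n_bins, seed=score_seed,
                                rescale=config.score.rescale)
        scores.to_frame().to_csv(os.path.join(out, "scores.tsv"), sep="\t",
                                 index=False, float_format="%.8g")
        record("score", score_seed, [os.path.join(out, "scores.tsv")],
               n_programs=len(gene_sets), n_references=len(mp_sets))
    else:
        record("score", score_seed, [], skipped="no gene programs to score")

    # ---- annotate --------------------------------------------------------
    ann_seed = stage_seed(config.seed, "annotate")
    if config.annotate.enabled and gps and mp_sets and scores is not None:
        _log_stage("annotate", ann_seed, config.annotate)
        mp_ref = MPReference.from_gmt(mp_sets, universe=expr_universe)
        table = annotate_gps(gps, mp_ref, expr, scores,
                             n_perm=config.annotate.n_perm,
                             confidence=config.annotate.confidence,
                             seed=ann_seed,
                             n_background=config.annotate.n_background,
                             n_bins=config.score.n_bins)
        table.to_csv(os.path.join(out, "annotation.tsv"), sep="\t", index=False,
                     float_format="%.8g")
        record("annotate", ann_seed, [os.path.join(out, "annotation.tsv")])
    else:
        record("annotate", ann_seed, [], skipped="no GPs or no reference sets")

    # ---- integrate (each line as a dataset) ------------------------------
    if config.integrate.enabled and len(lines) >= 2:
        datasets = [expr.subset_cells(np.flatnonzero(expr.line_labels == line))
                    for line in lines]
        joint = joint_center(datasets, labels=[str(line) for line in lines])
        n_pcs = min(config.integrate.n_pcs,
                    min(config.integrate.top_genes, joint.values.shape[0]),
                    joint.values.shape[1])
        pcs = joint_pca(joint, top_genes=config.integrate.top_genes, n_pcs=n_pcs)
        pc_df = pd.DataFrame(pcs.scores, columns=[f"PC{i+1}" for i in range(n_pcs)])
        pc_df.insert(0, "cell_id", pcs.cell_ids)
        pc_df.insert(1, "dataset", pcs.dataset_labels)
        pc_df.to_csv(os.path.join(out, "pc_scores.tsv"), sep="\t", index=False,
                     float_format="%.8g")
        files = [os.path.join(out, "pc_scores.tsv")]
        extra = {}
        if scores is not None and len(gene_sets) >= 2:
            first_two = list(gene_sets)[:2]
            joint_ids = [f"{line}:{cid}" for line, cid in
                         zip(expr.line_labels, expr.cell_ids)]
            ps = pd.DataFrame(
                {name: scores.rescaled[name].to_numpy() for name in first_two},
                index=pd.Index(joint_ids))
            pair = select_pc_pair(pcs, ps,
                                  r_threshold=config.integrate.r_threshold,
                                  top_pcs=n_pcs)
            pair.correlations.to_csv(os.path.join(out, "pc_correlations.tsv"),
                                     sep="\t", float_format="%.6g")
            files.append(os.path.join(out, "pc_correlations.tsv"))
            extra = dict(chosen_pair=(list(pair.chosen) if pair.chosen else None),
                         qualifies=pair.qualifies)
        record("integrate", 0, files, **extra)
    else:
        record("integrate", 0, [], skipped="disabled or single line")

    manifest["status"] = "complete"
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: str) -> None:
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
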