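# Methods

This note documents the models, parameter choices and numerical conventions
behind `senprog`, and what the synthetic-data generator does and does not
emulate.

## Preprocessing

Cells are filtered by five rules on the raw counts: total UMIs ≥ 500,
detected genes in [200, 8000], novelty score > 0.80, mitochondrial count
fraction < 10 %; genes must then be expressed (count > 0) in strictly more
than 0.1 % of the retained cells, evaluated on the post-cell-filter matrix.
Two readings of "log10 genes per UMI" exist; the implemented default is the
community novelty score log10(detected genes)/log10(total UMIs), because the
literal log10(genes/UMIs) is negative for every real cell and could never
clear a 0.80 threshold. The literal reading remains available as
`QCParams(novelty_mode="log_of_ratio")`. The mitochondrial rule is applied
to the fraction of *counts* (the standard convention); a fraction-of-genes
reading would need a different threshold scale. Boundary conventions are as
printed: the UMI and gene-count bounds are inclusive, the novelty and
mitochondrial rules strict.

These defaults presume genome-wide libraries. On a small simulated panel
(e.g. 200 genes) a cell physically cannot detect 200+ genes at novelty
> 0.80 — log10(200)/log10(4000) ≈ 0.64 — so pipeline runs on panel-scale
data use proportionally scaled QC settings (min_genes = 50, novelty > 0.5,
mito < 25 %). The thresholds are configuration, not constants, precisely
so that the same code serves both regimes.

Normalization is counts-per-million followed by log2(x+1). The TPM name is
kept for continuity with the expression-matrix convention, but no
gene-length term exists for 3' UMI data, so TPM ≡ CPM here. The NMF
substrate is the per-gene mean-centered matrix with negatives clipped to
zero; the subtracted means are stored so centering is reversible up to the
clipped mass.

## NMF programs

NMF is run per line (lines are factorized individually, never pooled) at
every rank K in {6, 7, 8, 9} using coordinate-descent Frobenius NMF with
NNDSVD initialization whose zero entries are perturbed by small seeded
random values ("nndsvdar"). This makes runs deterministic given a seed
while avoiding the zero-locking of plain NNDSVD. Convergence: relative
error change < 1e-4 or 500 iterations. Each run's seed derives from the
(line, K) pair, so adding a rank does not shift other ranks' results.
Components are summarized by their top 50 genes by basis coefficient;
coefficient ties break by gene id ascending so extraction is deterministic.
Matrices with fewer than 50 genes yield shorter programs flagged `short`.

## Consensus criteria

Overlap between two programs is the shared-gene count of their top-50
lists. Criterion 1 (cross-rank, within line) accepts at ≥ 35 shared genes;
criterion 2 (cross-line) at ≥ 10; both are inclusive ("at least") and are
evaluated against the full pre-filter program set. The greedy
redundancy scan (criterion 3) ranks robust programs by their similarity to
other lines' programs — implemented as the maximum Jaccard index to any
other-line program, with the mean of per-line maxima available as
`ranking="mean_of_max"` — and excludes a program when a previously
selected same-line program overlaps it *strictly* above 10 genes (the
wording distinguishes "at least 20 %" from "> 20 %", and so does the code).
Rank ties break by (line, K, component) ascending. When programs are
shorter than 50 genes, every threshold rescales as
ceil(fraction × shorter-list length).

Selected programs are clustered by average-linkage (UPGMA) agglomeration
on 1 − Jaccard distance; the tree is cut to a requested cluster count
(default 7) because the biological grouping this step models was a manual
call on the dendrogram — the cut level is the one genuinely free knob, and
it is exposed rather than hidden. A cluster's signature is the set of genes
present in ≥ 40 % (inclusive, ceil) of its member programs, ordered by
occurrence then gene id.

## Background-matched scoring

For a query set of n genes, 1,000 background sets of size n are drawn by
binning all genes into 30 equal-frequency bins of mean expression and
replacing each query gene with a draw from its bin (without replacement
within a set, so each background set reproduces the query's per-bin
histogram). Per cell, activity is the mean of the mean-centered expression
over the set, and

p = (1 + #{backgrounds with higher activity}) / (1 + 1,000).

The pseudocount keeps p strictly positive, so −log10 p is always finite;
ties count as not exceeding. Scores are rescaled linearly to [0, 1] per
program across *all* scored cells (per-line rescaling is available), since
cross-line score comparison is the point of a shared consensus program.
Under the null — query exchangeable with its backgrounds — the exceedance
count is uniform on {0..1000} and p is uniform to within 1/1001, which the
test suite verifies by a Kolmogorov–Smirnov test at 500 cells.

## Annotation

GP–reference similarity uses two statistics: mean Jaccard between each
member program's top-50 list and the reference set, and Pearson correlation
of per-cell scores. Permutation thresholds replace each member program's
gene list with a uniform random same-size draw from the scored matrix's
gene universe, 100 times, and pool the permuted statistics across all
(GP, reference, permutation) triples; the threshold is the 99.9 % quantile
of each pooled null. Pooling is deliberate: 100 permutations of a single
pair cannot support a 99.9 % quantile, but the pooled null across a
GP × reference grid can. For the correlation null, each permuted GP is
scored with 200 background sets (the jaccard null needs no scoring); the
correlation statistic is insensitive to the background count, which only
sets the granularity of p.

Hypergeometric overlap tests use the upper tail (P[X ≥ observed]); the
universe defaults to the genes detected in the scored matrix and is
overridable, since overlap p-values are only meaningful relative to a
stated universe. Benjamini–Hochberg adjustment is applied across the full
GP × reference table.

Representative-gene selection for a secreted program takes the union of
two routes: (A) genes with secretion log2 fold-change strictly above 2 in
at least one senescence condition of a SASP table AND detection frequency
equal to 1 — implemented as detected in every line, with a per-cell
fraction reading available — and (B) genes shared with companion program
sets. Each selected gene is tagged with its route(s).

## Integration

Datasets are restricted to shared genes, mean-centered per gene within
each dataset (removing dataset-level offsets without attempting batch
correction), and concatenated. PCA runs on the 4,500 genes with the
highest mean pre-centering expression — centered means are zero by
construction, so the ranking must use the pre-centering values; matrices
with fewer genes use all of them. For display, the PC pair maximizing the
minimum |r| against two program scores is chosen among the first 10 PCs,
subject to |r| > 0.35 for each (two-sided); when no pair qualifies the
full correlation table is returned with an explicit status rather than an
error.

## Drug screens

Viability is each well's ATP signal over the mean DMSO signal; the z-score
uses the sample (n−1) control SD. The growth rate is the ratio of
(drug day6/day4) to (control day6/day4) mean sizes. The median-effect fit
regresses log10(fa/(1−fa)) on log10 D; fa = 1 − viability is clipped to
[0.005, 0.995] before fitting (the log-odds is undefined at 0/1) with
clipped points flagged. The combination index is the mutually exclusive
form CI = Σ dᵢ/Dxᵢ; the mutually nonexclusive variant (extra
d₁d₂/(Dx₁Dx₂) term) is a flag. Calls use |log10 CI| ≤ 0.1 as an
"additivity" band — an exact zero is meaningless under measurement noise —
while the raw CI is always reported.

## Synthetic data: what it emulates, and what it does not

The count generator produces UMI-like matrices: lognormal baseline gene
means shared across lines (μ = 0, σ = 0.5 on the log scale), per-cell
library sizes uniform in [2,000, 6,000] for cells with no active program,
negative-binomial sampling, a 5 % mitochondrial gene subset named with the
`mt-` prefix, and planted programs that multiply their genes' expected
counts by a configured factor (default 8) in a configured fraction of
cells (default 30 %, exact per line after rounding). Rank-unstable
programs are planted as two half-gene-set, complementary-cell-subset
variants so a merged component appears only at some ranks — a true
negative for the cross-rank criterion. Line-specific programs are true
negatives for the cross-line criterion.

Gene-level noise follows a two-population dispersion model: a stable
majority at NB overdispersion α = 0.1 and a highly-variable minority
(45 % of genes) at α = 3.0, echoing the orders-of-magnitude spread of
per-gene dispersion estimates in real UMI data. Planted program genes are
drawn (disjointly across programs) from the stable pool. This choice is
load-bearing: noise-driven NMF components concentrate their top genes on
the highly-variable population, which keeps them nearly disjoint from
program gene lists. Genome-wide data has this property automatically —
two random 50-gene lists from 18,000 genes share ~0 genes — but on a
200-gene panel two random 50-gene lists share ~12 genes, which would
exceed the 10-of-50 inter-line criterion by chance alone and make
overlap-based filtering vacuous. The two-population model restores, at
panel scale, the signal/noise gene-population separation the consensus
filter relies on.

What the generator does **not** emulate: doublets, ambient RNA,
batch/chemistry effects, gene-length bias, cell-cycle covariation among
"noise" genes, or realistic gene-gene correlation beyond the planted
programs. Passing tests therefore demonstrate that the pipeline's logic is
correct and discriminates planted structure from overdispersed noise under
the stated model — not that it is robust to every artifact of real
droplet data.

Plate simulation: DMSO wells carry a configured baseline ATP signal; drug
wells follow the median-effect curve scaled by a per-drug maximum effect,
with optional Gaussian noise; organoid sizes grow by a control factor
(default 2.0 from day 4 to day 6) suppressed proportionally to the
affected fraction. With zero noise the whole
normalize → fit → combination-index chain is exact to numerical precision,
which the round-trip tests assert at 1e-6 relative tolerance.

## Problem sizes and determinism

Default test and acceptance problem sizes are 3 lines × 300 cells × 200
genes for the pipeline (seconds per run) and 500 cells × 1,000 background
sets for scoring calibration; these are the scales at which the planted
effects are comfortably detectable while keeping the suite fast. Every
random step takes a seed; pipeline stages derive their seeds as
sha256(global_seed:stage), and per-program background seeds derive from
the seed plus the gene-set content, so identical gene sets score
identically and reruns with one config are byte-identical.

## Known limitations

- The consensus filter's thresholds are fixed gene counts (35/10/>10 of
  50); they are the printed convention, not adaptive quantities, and their
  discriminative power depends on the list-size/genome-size ratio (see the
  generator discussion above).
- The UPGMA cut count is user-chosen; no automatic cluster-number
  selection is attempted.
- Permutation thresholds use a pooled null; per-pair nulls would need far
  more than 100 permutations.
- NMF solutions are local optima; determinism is per seed, and different
  seeds can yield slightly different component boundaries (the consensus
  step exists precisely to absorb this).
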