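# Methods

This note documents the models and procedures behind `crossatlas`, the
assumptions they make, the parameters that matter, and the places where
the design was genuinely open and a choice had to be made.

## Synthetic paired datasets

The generator produces count matrices for two species, A and B, with a
known ortholog structure and known cell-type programs, so that every
downstream stage can be scored against ground truth.

**Gene space.** Each species carries `genes_per_species` genes (default
3000). The first `n_one2one` (2000) form a 1:1 ortholog bijection
(A_i ↔ B_i); the next block forms 1:many pairs (each of `n_one2many`
A-genes maps to two B-genes); the remainder are species-private, with the
final genes reserved as mitochondrial and rRNA covariates whose baseline
rates are scaled so their expected share of each cell's transcripts
matches `mito_frac_mean` (0.02) and `rrna_frac_mean` (0.05). Baseline
expression per gene is log-normal (log-mean ln 0.25, log-sd 1.0) — the
strong mean heterogeneity of real transcriptomes is what makes variable-
gene selection meaningful. Ortholog pairs share one baseline draw so
background expression is comparable across species.

**Cell types and programs.** `n_types_shared` (8) types exist in both
species; `n_types_specific_A/B` (1 each) exist in only one. Each type has
a disjoint program of `program_size` (30) genes whose mean is multiplied
by `program_effect` (10). Shared-type programs are drawn from the 1:1
pool and mapped through the bijection, with a fraction `divergence_frac`
(0.2) of each species' copy rewired to other 1:1 genes — matched types
therefore share 80% of their program, which is what the marker-overlap
statistics are meant to detect.

**Where species-specific programs live.** `specific_ortholog_frac`
controls how much of a specific type's program sits on 1:1 ortholog genes
(deployed in only that species) versus species-private genes. The default
is 1.0: a cell state whose program lives entirely on private genes is
*invisible* after 1:1 restriction — its cells are indistinguishable from
background in the shared space, and the A-only and B-only populations
would collapse into one well-mixed cluster no integration method could
separate. The biologically observed analogue (a germline-like population
skewing one species' contribution) is precisely the case where the
distinguishing genes exist in both genomes but are expressed in one, and
that is the case the default emulates. Setting the fraction below 1
grades the difficulty; 0 reproduces the fully-private design.

**Counts.** Conditional on cell c and gene g, counts are negative
binomial via gamma-Poisson: mean μ = baseline_g × effect × t_g × l_c with
per-cell library factor l_c ~ logNormal(0, 0.3), mild per-timepoint
per-gene shifts t_g ~ logNormal(0, 0.05) (timepoints pool into one atlas,
so shifts are deliberately small), and variance μ + μ²·`nb_dispersion`
(0.5). The moment law is tested with the library-size factor switched
off, because marginally over l_c the variance is inflated by design.
Each dataset draws from its own RNG stream keyed by (seed, species), so
outputs are bit-reproducible and independent of generation order.

**Defaults and scale.** The default design yields 2700 cells per species
(9 types × 3 timepoints × 100 cells). All end-to-end checks
(integration skew/mixing, marker recovery, RF behavior) run at this
scale; one full run takes ~10 s on one CPU.

**What the generator does not emulate** — doublets, ambient RNA,
spliced/unspliced kinetics, cell-cycle structure, continuous trajectories
between types, or realistic dropout-vs-mean relationships beyond what the
NB law implies. Passing tests demonstrate that the pipeline's logic
recovers planted discrete structure under NB noise; they do not certify
performance on real tissue.

**Bulk triplet.** One "culture" is split into embryo / cells / nuclei
aliquots: per-gene expectations are log-normal, the two isolation methods
multiply each gene by 2^N(0, σ) with method-specific σ, and all three
vectors are Poisson-sampled. σ is recoverable as the sd of the per-gene
log2 fold-change distribution after quantile normalization; with 20,000
genes and mean depth 500 the Poisson contribution to that sd is ~0.07 in
quadrature, small against the σ values of interest (~0.5–0.7).

## Quality control

Per-cell metrics are genes detected, total counts, and mitochondrial
fraction (0 for empty cells). Filtering removes a cell only when a metric
is *strictly* outside its bounds — "more than 5% mitochondrial" removes
5.1% and keeps 5.0% — and the report attributes each removed cell to every
rule it violates. Thresholds are per-sample configuration, since real
datasets need manually chosen cutoffs.

## Atlas construction

**Normalization** is log1p(count / cell_total × 10⁴) followed, when
nuisance covariates are supplied (rRNA content, mitochondrial fraction),
by per-gene OLS regression: value ← residual + gene mean. This is a
deliberately simple variance-stabilizing transform with linear covariate
removal, not a regularized negative-binomial regression; the provenance
dict records exactly what was applied. The pipeline contract downstream
only requires finite, covariate-cleaned values.

**Highly variable genes** are ranked by standardized variance: the
expected log10 variance of a gene is predicted from the *rank* of its
mean (quadratic fit over genes with positive variance), and the variance
of expectation-scaled z-scores, clipped at √n_cells, is the score. Using
mean ranks instead of log-means makes selection invariant under monotone
(e.g. constant-shift) transforms, which in turn makes the integration
exactly invariant to a global shift of one dataset. Ties and the
degenerate constant-matrix case fall back to lexicographic gene order, so
selection is deterministic.

**PCA** is centered, per-gene unit-scaled, computed by randomized SVD
with a fixed internal seed; component signs are fixed by making each
loading vector's largest-magnitude entry positive, so repeated calls are
bit-identical.

**Number of PCs.** The elbow rule returns the smallest i such that
component i contributes < 5% of total sd and every consecutive drop from
i onward is < 0.1% of total sd (i.e. i sits past the last appreciable
drop), requiring sd_i strictly below sd_1 so a flat spectrum has no
elbow. On the default simulation this lands exactly on the planted
dimensionality (10 components for 10 types). A config override replaces
the rule where the component count was fixed by inspection.

**Graph and clustering.** The kNN graph uses k = 20 Euclidean neighbors
in PC space; edges are weighted by the Jaccard overlap of the two cells'
neighbor sets (self included) and pruned below 1/15 — the conventional
shared-nearest-neighbor weighting. Louvain community detection
(python-igraph multilevel, seeded) maximizes modularity at the configured
resolution; labels are relabeled by decreasing cluster size so "cluster
0" is always the largest. UMAP is provided for visualisation only and is
deterministic at a fixed seed.

## Marker genes

For each cluster versus all other cells, a gene is admitted when
expressed in ≥ `min_pct` (5%) of the cluster's cells (in-cluster only by
default — an option extends the gate to both groups) and its natural-log
fold change of de-logged means with pseudocount 1 is ≥ `min_logfc`
(0.25). Admitted genes are Wilcoxon rank-sum tested (exact enumeration
for combined n ≤ 12 without ties, otherwise the normal approximation
with tie and continuity corrections); p-values are Bonferroni-multiplied
by the *total* gene count of the matrix (conservative, and the convention
of the ecosystem this mirrors); rows with adjusted p ≤ α (0.05) and
positive fold change are reported.

**A calibration caveat.** The rank-sum test is calibrated for labels
chosen independently of the data: on one-type null data with randomly
permuted labels, marker tables are empty in ≥ 95% of seeds (each seed's
residual risk is the Bonferroni familywise α per cluster). But testing
clusters that were *derived from the same data* double-dips: on
structureless data, Louvain partitions noise and a handful of
Bonferroni-significant "markers" of those noise clusters appear in
essentially every seed. This is a property of the standard
cluster-then-test workflow itself, not of this implementation, and users
comparing clusters they obtained from the same matrix should treat
borderline markers accordingly.

## Cross-species machinery

**Shared gene space.** The 1:1 subset of the ortholog table is validated
as a bijection; pairs are retained when each side's gene has nonzero
counts in ≥ `min_cells` (2) cells of its dataset. Species-A rows are
renamed to the orthologous species-B ids, so both matrices share one
gene universe and marker sets from either side can be intersected.

**Integration.** Anchor features are the shared HVGs (summed per-dataset
ranks, up to 3000). Each dataset's feature submatrix is standardized per
gene within dataset; the top canonical-correlation cell loadings (2×dims
components of the cross-covariance SVD, rows L2-normalized) define the
space where mutual nearest neighbor pairs (`k_anchor` = 5) become
anchors. Anchors are then *filtered*: the reference cell must be among
the query cell's `k_filter` = 200 nearest reference cells in expression
space. This filter is load-bearing — CCA places populations with no
counterpart in the other dataset near each other, and unfiltered anchors
between two mutually-unmatched populations drive a correction that
collapses them into one spurious mixed cluster. Surviving anchors are
scored by shared-neighbor overlap in joint CCA space (quantile-rescaled
to [0, 1]); each query cell's correction is the score- and
Gaussian-weighted average of its `k_weight` = 100 nearest anchors'
reference-minus-query difference vectors, with bandwidth equal to the
distance to the k_weight-th anchor. Joint PCA (dims = 10), the k = 20
SNN graph and Louvain complete the integrated clustering. The first
dataset is the reference and is never modified.

The integration contract is behavioral, not numeric: types present in
both species form clusters whose size-normalized minority fraction stays
≥ 1/3, and a planted single-species type yields a cluster ≥ 90% one
species. Both hold across seeds at the default design, with observed
skews 0.93–1.0 and minorities 0.40–0.50.

**Composition.** Direction `of_integrated_cluster` weights each cell by
the inverse of its species' total cell count and normalizes within the
cluster (rows sum to 1); it is invariant under duplicating every cell of
one species. Direction `of_origin_cluster` is the unweighted fraction of
each origin population landing in each integrated cluster (columns sum
to 1).

**Overlap statistics.** RF = k/(n₁n₂/N) and p = P(X ≥ k) under
X ~ Hypergeometric(N, n₁, n₂), computed with scipy's stable tail (exact
agreement with exhaustive subset enumeration is tested for every
(k, n₁, n₂, N) with N ≤ 12, and the tail does not underflow at the
~10⁻¹⁹ magnitudes that arise in practice). For cross-species comparisons
the universe defaults to the retained shared-space size — the expressed
subset, not the full identified 1:1 list, since sets can only be drawn
from genes that can appear as markers — and for within-species
comparisons to a configured annotation total (default 27,818). Text
rendering reports p as an upper bound ("p < 1e-18") while the stored
value keeps full precision.

## Bulk concordance

Quantile normalization replaces each sample's sorted values with the
cross-sample rank means; genes tied within a sample receive the mean of
the target values their rank span covers. With that tie rule, exact
idempotence holds on tie-free data (and is tested there); under ties a
second pass changes values slightly because tie spans collapse the
target distribution differently per sample — an inherent property of
tie-averaged quantile normalization, not an implementation artifact.
Spearman ρ (Pearson on mid-ranks) and Kendall τ-b are both reported,
since the two are easy to conflate in figure captions; both are
undefined (an error) for constant profiles. Per-gene log2 fold changes
use pseudocount 1; the summary reports mean, sample sd (n−1) and median.
The sd is the decision statistic: the isolation method with the smaller
log2FC sd tracks the reference profile more faithfully, and on synthetic
triplets the planted bias sds (0.558, 0.683) are recovered within a few
percent at 20,000 genes.

## Pre-mRNA GTF utility

For single-nucleus data, unspliced reads must count toward genes; the
utility rewrites a GTF so each transcript's exon set becomes one exon
spanning min(start)–max(end), strand and attributes preserved, non-exon
lines untouched (1-based inclusive coordinates throughout, never
converted). Collapse is per-transcript by default; a per-gene mode is
offered because annotation pipelines differ on this point. The operation
is idempotent.

## Pipeline and reproducibility

`run_pipeline` executes inputs → QC → per-species atlases → markers →
1:1 restriction → integration → composition → overlap requests from one
YAML config, writing TSV/CSV/JSON artifacts plus a provenance record
(config hash, package versions, completed stages). No stage mutates its
inputs; all randomness flows from config seeds, so a rerun with the same
config reproduces identical outputs. On failure, partial outputs and a
MANIFEST of completed stages are preserved and the CLI exits nonzero
(1 for validation errors, 2 for runtime failures).

## Known limitations

- Exactly two datasets/species per integration; 1:many and many:many
  orthologs are excluded rather than modeled.
- The normalization stand-in removes only *linear* covariate effects.
- Marker p-values inherit the double-dipping caveat above.
- The elbow rule assumes a spectrum with a genuine plateau; pathological
  spectra should use the explicit PC-count override.
- Synthetic types are discrete; the pipeline's behavior on continuous
  differentiation trajectories is untested by design.
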