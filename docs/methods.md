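# Methods

## Problem and model

`embryomap` implements a reference-and-query workflow for single-cell RNA-seq:
an integrated atlas is built once from several batches spanning a developmental
series, and new datasets are then placed into that *frozen* atlas and annotated.
The central requirement is replayability: every transformation applied during
construction — normalization scale, feature selection, grand centering, the SVD
rotation, and each merge step's orthogonalization — is recorded so that a query
can be pushed through the identical sequence of maps without recomputing or
perturbing the reference.

The batch-correction model follows the mutual-nearest-neighbor (MNN) paradigm:
cells that are reciprocally within each other's k nearest neighbors across a
batch boundary are assumed to be the same cell type, and the batch effect is
assumed approximately orthogonal to the biological subspace. Both assumptions
are load-bearing. When a query shares no populations with the reference, MNN
pairs are spurious; the pipeline therefore gates predictions on Spearman
correlation to the reference and on MNN-pair support, and abstains
(`nonrelated`, `ambiguous`) rather than forcing a label.

## Pipeline stages and their parameters

**QC** (`qc_filter`). Cells kept when the expressed-gene count is at least
`min_genes` (default 2,000, full-length data) and the mitochondrial count
fraction is strictly below `max_mito_frac` (default 0.125); an optional
`max_genes` ceiling guards against doublets in droplet data. Mitochondrial
genes are then removed and genes kept when expressed in at least
`min_cells_per_gene` (default 5) remaining cells.

**Size factors** (`compute_size_factors`). Default method is
pool-and-deconvolve: cells ordered by library size on a ring are summed into
sliding pools of sizes {21, 41, 61, 81, 101} (capped at the cell count); each
pool's factor is the median gene-wise ratio to the average pseudo-cell, and
per-cell factors solve the stacked linear system by least squares (LSQR), with
low-weight anchor rows tying each cell to its library-size factor to keep the
system well-posed. A single cluster is used; no pre-clustering. Factors are
clamped positive and rescaled to mean 1. A plain library-size method is
available.

**Cross-batch rescaling** (`multibatch_rescale`). Each batch's factors are
multiplied by s_b = (batch coverage) / (minimum batch coverage), where coverage
is the mean of total count over size factor; expression is log2(1 + count /
(factor · s_b)). The minimum coverage (the *target*) and each s_b are recorded;
a query is rescaled against the recorded target, not against its own minimum.

**Integration features** (`select_integration_features`). Per batch, genes are
ranked by variance of log expression divided by a lowess trend fit of variance
against mean (span 0.3). Stage 1 picks `n_hvg_stage1` (default 2,000) genes by
votes — in how many designated early-stage batches the gene ranks inside the
top `n_hvg_stage1` — tie-broken by median rank and then by name; stage 2
extends to `n_hvg_total` (default 4,000) with the same vote over all batches.
If fewer shared genes exist than requested, all are taken and the selection is
flagged truncated.

**Subspace** (`multibatch_pca`). Cosine-normalized cells from all batches are
concatenated; the per-gene grand means are removed; a plain (unweighted) SVD
supplies the top `n_pcs` (default 50) left singular vectors. Signs are fixed by
making each component's largest-magnitude gene loading positive, so rotations
are platform-independent.

**Merging** (`merge_batches`). Batches are merged sequentially in developmental
order with MNN k = 20 per side (`k_mnn_ref`). Pair vectors are smoothed over
the incoming batch with a Gaussian kernel of bandwidth σ = `ndist` (default 3)
times the median distance of paired cells to their k-th nearest within-batch
neighbor. Variance adjustment then scales each cell's correction (factor ≥ 1)
along the mean pair-vector direction until the cell's quantile along that
direction matches the reference distribution; components orthogonal to the
direction are untouched. Finally both sides are orthogonalized along the unit
mean-correction direction to the pooled mean projection, and the direction,
target mean and bandwidth are recorded. If the mean pair vector is numerically
zero (coincident batches), the step records a degenerate marker and performs —
and later replays — the identity instead of collapsing variance along a noise
direction.

**Embeddings and clusters.** One UMAP model per requested dimension (2 for
display, `latent_dim` = 20 by default for classification) with
`umap_neighbors` = 30, `umap_min_dist` = 0.3 and a fixed seed; models support
`transform` for out-of-sample points. Leiden clustering runs on a
shared-nearest-neighbor graph (Jaccard edge weights over `umap_neighbors`-NN
sets) at `leiden_resolution` = 1.0 with a fixed seed.

**Classifiers** (`train_lineage_classifiers`). One one-vs-rest RBF SVM per
lineage in the latent space, class weights balanced. Hyperparameters are chosen
per lineage by stratified 5-fold CV over C ∈ {2⁻², …, 2⁶} × γ ∈ {2⁻⁸, …, 2²}
(both grids configurable), maximizing mean Cohen's kappa on the binary task;
ties resolve to the first grid entry, making selection deterministic. The
winner is refit with sigmoid (Platt) probability calibration. Lineages under 10
cells skip the search (mid-grid parameters, warning); under 2 cells is an
error.

**Query projection** (`project_query`). Gene coverage of the reference feature
set below 80% is an error; missing features are zero-imputed and counted.
Normalization replays the recorded method and target coverage. MNN pairs are
searched in the orthogonalized subspace by default (a `mnn_space="cosine"`
switch searches on unit-vector values instead), per reference dataset, on
chunks of `subsample_size` = 200 cells over `n_repeats` = 5 seeded shuffles
with K = 30 (K = 5 when the query has < 50 cells); pairs are unioned and
deduplicated. Filters: (1) query cells linked to both lineages of a configured
mutually exclusive pair (default TE/amnion) lose all pairs; (2) pairs with
Spearman < `corr_threshold` = 0.5 are dropped (the pair-level cutoff reuses the
gating threshold since no separate value is specified anywhere); (3) lineages
whose top `top_n_corr` = 20 pair correlations all fall below the threshold lose
every pair. Spearman correlations are computed on the integration-feature unit
values with midrank ties. The surviving pairs drive the same kernel-smoothed,
variance-adjusted correction as in construction, applied to the query only.

**Prediction** (`predict_identities`). Argmax of the per-lineage calibrated
probabilities, ties broken by lineage name and flagged. Gates, in order:
`nonrelated` (mean Spearman over the top-20 correlated reference cells strictly
below 0.5) overrides everything; probability below 0.5 (strictly — exactly 0.5
is assigned) yields `ambiguous`/`below_threshold`; a winning lineage absent
from the filtered pair set's lineages yields `ambiguous`/`no_mnn_support`.
Support is dataset-scoped by default; `per_cell_mnn_support=True` restricts
support to each cell's own pairs. With neighborhood aggregation (triggered when
the median expressed-gene count falls below 5,000, or forced), predictions are
made on aggregated profiles and inherited by member cells, conflicts resolved
by highest probability; cells in no neighborhood are `nb_failed`.

**Neighborhoods** (`make_neighborhoods`). ⌈`nhood_prop`·n⌉ index candidates
(default prop 0.15) are sampled uniformly, refined to the kNN-set member
closest to the set's mean, deduplicated; a neighborhood is the index cell plus
its `nhood_k` nearest neighbors and its profile is the exact sum of member raw
counts (a cell in several neighborhoods contributes once to each — multiplicity
follows membership). The kNN graph is built on a log-normalized PCA restricted
to the top quartile of variable genes (capped at 2,000), the standard practice
for droplet data.

**Markers and consensus DEGs.** Two-sided Wilcoxon rank-sum on log expression
(exact null when group sizes are small and tie-free, asymptotic otherwise),
Bonferroni adjustment over tested genes; log2 fold change on de-logged means
with pseudocount 1. Module scores are mean program expression minus the mean of
expression-bin-matched controls (24 bins, 100 controls per program gene,
seeded). Stouffer combination uses Z = Σwᵢzᵢ/√(Σwᵢ²); for two-sided inputs each
p is halved, signed by fold-change direction, combined and re-two-sided.
`consensus_deg` applies configurable criteria — mean expression in the
upregulated group, fold-change floor in ≥ m comparisons, adjusted-p ceiling in
≥ m comparisons, expressing-fraction bounds, Bonferroni-adjusted combined p,
sex-chromosome exclusion — reproducing the strict all-comparisons variant, the
3-of-n + combined-p variant, and the variant without the fraction rule.

## Synthetic data: what it emulates and what it does not

`simulate_reference_series` draws a branching five-lineage hierarchy
(root → inner/outer → two terminal fates) shared by several batches: gamma-
distributed baseline gene programs with 50 disjoint marker genes per lineage
(log2FC 2 over the parent program), gene-wise log-normal batch factors
(sd 0.15), log-normal library sizes (median 50,000 counts), and gamma-Poisson
(negative binomial, dispersion 0.1) counts over 20,000 genes. Queries reuse the
identical programs through named child RNG streams; sparse mode binomially
downsamples each cell to 5% depth, mimicking droplet data (< 20% of deep-mode
expressed genes per cell at genome scale). `simulate_unrelated` permutes gene
identities and redraws programs so queries genuinely fall outside the
reference's scope.

The generator reproduces the statistical structure the method relies on —
hierarchical lineage programs, multiplicative batch distortions (which appear
as near-constant offsets in the cosine/SVD subspace, so MNN correction is
genuinely exercised), library-size variation, NB noise, droplet sparsity. It
does **not** emulate real embryo biology: no real gene names or pathway
structure, no doublets or ambient RNA, no continuous differentiation gradients
(lineages are discrete clusters), and batch effects are linear in log space.
Passing tests therefore demonstrate correctness of the machinery and recovery
under the stated assumptions, not performance on real embryo datasets, where
lineage boundaries are softer and batch effects messier.

## Problem sizes used in tests and the acceptance script

Desk-scale runs use 1,200 genes (25 markers per lineage), 3 batches × 5
lineages × 40 cells, a 30-dimensional subspace with a 10-dimensional latent
space, 400 integration features (200 first-stage), 15 UMAP neighbors and a
reduced SVM grid — the whole suite runs in a couple of minutes on one CPU.
Genome-scale defaults (20,000 genes, 50-PC subspace, 20-D latent, 4,000
features) are exercised where cheap, e.g. the sparse-depth property. Two sizes
are deliberately larger than the minimum: sparse-mode queries use 300 cells
(60 per lineage), because droplet datasets are large in practice and a k = 10
neighborhood graph over only 150 shallow cells crosses lineage borders; and the
label-shuffle classifier null uses ~300 held-out cells so the null kappa's
sampling noise (sd ≈ 1/√n) is small relative to the 0.1 bound being checked.

## Numerical choices, tie-breaks, degenerate inputs

- Nearest-neighbor searches break distance ties by index (stable argsort);
  MNN output is therefore reproducible across platforms.
- SVD signs are fixed per component by the largest-magnitude loading; rank
  deficiency reduces the subspace dimension with a warning.
- A zero kernel bandwidth (all paired cells coincident) falls back to the
  unweighted mean of pair vectors, with a warning.
- A numerically zero mean pair vector marks the merge step degenerate: no
  orthogonalization is applied or replayed. This protects coincident batches
  from having real variance collapsed along a noise direction.
- Zero expression columns survive cosine normalization as zeros and are
  recorded; zero-total cells are an error naming the cell.
- Classifier grid ties resolve to the first (smallest C, then γ) entry.
- Probability exactly at the threshold is assigned; correlation exactly at the
  threshold is not flagged (both thresholds are one-sided by construction).
- Combined p-values of exactly 0 are clamped to the smallest positive float
  with a warning.

## Design choices where the design was open

- **Serialization**: a directory with a JSON manifest (schema version, config,
  shapes, SHA-256 checksums), an HDF5 file for numeric/string arrays, and
  pickled UMAP/classifier models. Checksums are verified on load and the
  round trip is bit-exact, so saved references produce identical projections.
- **MNN search space for queries**: the orthogonalized subspace by default;
  searching on cosine values directly is available via `mnn_space` since
  either reading of the procedure is defensible.
- **Stage-2 feature voting**: the same count-then-median-rank vote as stage 1,
  applied over all batches with stage-1 picks excluded.
- **MNN-pair support scope**: dataset-scoped (any pair to a lineage supports
  it for the whole query) by default, per-cell as an option.
- **Expression scale for the DEG mean-expression criterion**: normalized
  counts; the threshold (default 10) is configurable.
- **"Top marker" ordering** for module scores and marker summaries: adjusted p
  ascending, then fold change.

## Known limitations

- The sequential merge is order-dependent by construction; the recorded order
  is part of the model and must reflect developmental time.
- Orthogonalization removes one direction of real biological variance whenever
  the batch vector is not perfectly orthogonal to biology — inherent to the
  correction model.
- With duplicated or near-duplicated batches at the default k = 20, kernel
  smoothing over asymmetric pair sets leaves residual corrections of a few
  percent of the data scale (exactly zero only at k = 1); see the degenerate-
  merge note above.
- Correlation gating assumes the integration features are informative for the
  query; a query measuring a disjoint gene panel fails the 80% coverage floor
  rather than being silently zero-imputed.
- UMAP `transform` places new points relative to a fixed graph; queries far
  outside the reference manifold land unpredictably in 2-D, which is why
  predictions are gated on correlation and pair support rather than embedding
  position alone.
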