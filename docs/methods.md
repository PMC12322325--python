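# Methods

This note documents the models and procedures implemented in `oligoscore`,
the assumptions behind them, the defaults and why they were chosen, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Preprocessing

**QC.** Cells are retained when they express between 200 and 6,000 genes
(both bounds inclusive) and their mitochondrial read fraction (genes
prefixed `MT-`) is strictly below 5%. A zero-count cell has mitochondrial
fraction defined as 0 and is removed by the gene-count bound. The filter
is idempotent.

**Normalization.** Counts are library-size normalized to a scale factor of
10,000 and transformed with the natural log: `ln(1 + c/L * 10^4)`.
Natural log is used for expression values; log2 is reserved for fold
changes.

**Highly variable genes.** Genes are ranked by their variance z-scored
within 20 equal-occupancy mean-expression bins. This binned standardized
variance has the same intent as loess-based variance-stabilizing trends
but is deterministic and dependency-free. Ties break by raw variance
(descending) then gene symbol (ascending), so the ranking is total and
reproducible. 2,000 genes are kept for clustering, up to 4,500 for
prototype training.

**PCA.** Expression of the selected genes is centered, scaled to unit
variance (s.d. floor 1e-12) and clamped at +10 standard deviations before
eigendecomposition (performed on the smaller of the gene-gene covariance
or cell-cell Gram matrix; exact, deterministic). Component signs are fixed
by making the largest-magnitude gene loading positive. Requesting more
components than the matrix rank is an error unless truncation is
explicitly allowed. 30 components are used by default.

**kNN graph.** Exact Euclidean k nearest neighbors (k = 15), ties broken
toward the lower cell index via stable sort; the undirected graph is the
union symmetrization, so degrees can exceed k. No approximate-neighbor
shortcuts: the graph equals the brute-force result by construction.

**Clustering.** Louvain modularity optimization (resolution 0.5 by
default), deterministic given the seed; cluster ids are re-labeled by each
community's smallest cell index. Clusters are annotated by the cell type
whose marker genes have the highest mean z-scored expression; ties break
alphabetically with a warning.

## Prototype scoring

The scorer is a multinomial logistic model with an L2 penalty, trained on
the reference atlas's labeled subtypes over the top highly variable genes,
each standardized with training-set statistics (s.d. floor 1e-8) that are
frozen for query scoring. Query genes absent from the model contribute the
training mean (standardized 0); if more than half the model genes are
missing the query is rejected as unreliable. The softmax class
probabilities are the similarity scores; a cell is assigned its argmax
class only when the top score reaches `tau = 0.70`, otherwise it is
"unassigned". Because `tau > 0.5`, at most one class can qualify, so the
assignment is unique.

**Penalty selection.** `lambda` is swept over a 13-point log grid
(10^-3 ... 10^3) with 5-fold stratified CV; the trace records per-lambda CV
accuracy (with a 1.96*SD/sqrt(5) confidence half-width), held-out
log-likelihood, held-out mean top-class probability, the held-out
assignment rate (fraction of cells whose top probability clears `tau`),
the total absolute weight, and the training log-likelihood. On
well-separated classes CV *accuracy* is flat across the entire grid, so
any rule that consults accuracy alone drifts to a grid edge: the weakest
penalty leaves overfit weight on uninformative genes (which inflates
scores for cells that match no prototype), while the strongest shrinks all
scores toward 1/K and nothing reaches `tau`. The adopted rule therefore
selects the strongest penalty that (i) keeps CV accuracy within one
confidence half-width of the best, with the half-width floored at one
misclassified cell (1/n) so a perfect-accuracy fold set does not collapse
the band, and (ii) keeps the CV assignment rate at `tau` at or above 0.95.
Reference cells are all genuine prototype members, so a model that leaves
more than ~5% of them unassigned is over-shrunk; under that constraint
maximal shrinkage is preferred for generalization and for suppressing the
scores of cells that match no prototype. If no penalty reaches the
coverage floor, the most-covering eligible one is used. The seed affects
only CV fold assignment; the convex solver (L-BFGS, tolerance 1e-6) is
deterministic.

**Gene reduction.** Genes can be re-ranked by their maximum absolute class
weight and the model refit on the top-n at `lambda*`; a CV-accuracy drop
beyond 0.05 is logged as a warning.

**Composition tables.** Region × subtype fractions include the
"unassigned" bucket and sum to 1 per region. For recovery comparisons
against planted truth, fractions among threshold-passing cells only are
also used, matching how subtype matches are extracted in practice
(cells below `tau` are excluded from composition figures).

**Wheel plot.** Class k sits at angle 2πk/K on the unit circle and each
cell maps to the score-weighted average of the vertices: a one-hot score
lands exactly on its vertex, a uniform score at the origin, and every cell
inside the convex hull. The convention is "higher score = closer to the
vertex".

## Gene-module scoring

The score of a gene set in a cell is the mean normalized expression of the
set genes minus the mean over control genes drawn from the same
average-expression bins: genes are ordered by their mean across all cells
and cut into 25 equal-occupancy bins; each set gene contributes up to 100
controls sampled without replacement from its bin, excluding the set's own
genes (to prevent self-cancellation for large sets); bins smaller than the
control count contribute entirely. The score is exactly invariant to
adding a constant to all expression values, and a random gene set scores
approximately 0 on any data because its controls are expression-matched.
Sampling is seeded. Group summaries report n/mean/median/IQR per
(region × cell type) and two-sided rank-sum tests against the Control
region with Benjamini–Hochberg adjustment.

## Neighborhood differential abundance

Index cells are drawn uniformly (10% of cells by default), refined once to
the member of their neighborhood closest to the neighborhood's embedding
mean (ties to the lower index), and deduplicated; each neighborhood is the
refined index cell plus its graph neighbors on the k = 15 graph. Every
neighborhood is tested for condition imbalance with a two-sided Fisher
exact test on the 2×2 table (cells in/out of the neighborhood × condition),
with BH adjustment across neighborhoods, a log2 fold change on
in-neighborhood proportions with pseudo-proportion `0.5/min(N_A, N_B)`,
and a majority-label annotation. Cell groups present in fewer than 3
distinct samples are excluded beforehand.

This is a deliberate simplification of negative-binomial GLM pipelines for
neighborhood abundance: the object (neighborhood-level DA on a kNN graph)
is preserved, but the test is exact and dependency-light. Neighborhoods
may overlap and no graph-aware ("spatial") FDR weighting is applied.
Multi-region designs are analyzed as region-vs-Control pairs.

**Power limitation (known and quantified).** A neighborhood built at
k = 15 holds roughly 16–35 cells. For a 3-fold planted enrichment the
in-neighborhood condition composition is about 3:1, and a two-sided Fisher
test on ~30 cells has raw power ≈ 0.7 at α = 0.05; after BH at FDR 0.10
the measured detection rate for enriched-majority neighborhoods is about
0.5–0.6. Detecting 3-fold shifts at ≥80% per-neighborhood power would
require roughly twice the neighborhood size (k ≈ 40) or stronger effects;
this is an information limit of per-neighborhood testing, not of the
implementation (count-GLM alternatives face the same bound). Calibration
is unaffected: under permuted labels fewer than 5% of neighborhoods are
flagged at FDR 0.05.

## Ligand–receptor communication

For each (pair, sender type, receiver type) within a region, the statistic
is `0.5 * (mean ligand expression in senders + mean receptor expression in
receivers)` on normalized values. A combination is tested only when the
ligand is detected (count > 0) in ≥10% of senders and the receptor in ≥10%
of receivers. The null shuffles cell-type labels within the region (1,000
permutations, shared across combinations, seeded, with cells visited in
canonical id order so results do not depend on input column order); the
p-value uses the add-one convention `p = (1 + #{perm ≥ obs})/(1 + n_perm)`,
so it is never 0 and at most 1; significance is `p < 0.05`. Regions are
analyzed independently. Per-region sender × receiver matrices count
significant pairs; a long-format profile table supports dot-plot style
views of named pairs across regions.

Note that the type-I calibration of a label-permutation test presumes
label exchangeability. After library-size normalization, cell types with
strong expression programs have systematically diluted values at unrelated
genes (a composition effect), so even "pattern-free" genes are not
exchangeable across real type labels; calibration checks therefore shuffle
the type labels, which is the null the test actually addresses.

## Differential expression and over-representation

Two-sided Wilcoxon rank-sum per gene: exact enumeration when both groups
have ≤8 cells and no ties, otherwise the tie-corrected normal
approximation with continuity correction (the largest discrete gap between
the two at 8 vs 8 is 0.011). A completely constant gene returns p = 1.
log2 fold changes are computed on de-logged means with a pseudocount of 1,
so they are finite and exactly antisymmetric under group swap. BH adjusts
across genes. Two filter conventions exist and are never silently
substituted: "standard" (adjusted p < 0.05 and |log2FC| > 0.5) and
"volcano" (raw p, −log10 p > 1.5 and |log2FC| > 0.585), all strict
inequalities.

Over-representation is the hypergeometric upper tail `P[X ≥ k]` for the
overlap k of a query list with each GMT set intersected with the universe
(sets below 3 genes after intersection are skipped), BH-adjusted across
sets. No annotation databases are bundled; any GMT works.

## Synthetic data generator

Counts are negative binomial (gamma–Poisson) with dispersion θ = 2 and
per-cell log-normal library factors (σ = 0.35). Each of the seven
OL-lineage subtypes carries its canonical markers at 8× baseline
(μ0 = 0.3); major-type markers (OL, OPC, MG, AST panels) at 4×; and —
because real cell states differ across hundreds of genes, not only their
confident markers — an exclusive broad program of 40 genes at 4×. GPR17 is
planted in both COP and NFOL, making them the hardest pair to separate, as
transitional states are in practice. Filler genes get log-normal mean
heterogeneity (σ = 0.4). The 13 `MT-` genes are scaled per cell so the
mitochondrial fraction follows Beta(2, 78) (mean 2.5%, ~6% of cells above
the 5% QC bound), giving QC realistic work. The inflamed-microglia program
(24 canonical inflammatory genes) is elevated 4× in inflamed cells.

The query plants per-region compositions exactly (largest-remainder
allocation per sample, 3 samples × 200 cells per region), so zeros are
structural: Pre-OPC/NFOL at 10–12% in Control/NAWM, 0% in CA/CI, 4% at
edges; MOL depleted in cores; MG 3-fold enriched in CA vs Control with the
inflamed fraction raised in NAWM/CA/CA-edge. Ligand–receptor axes use a
low off-state baseline (mean 0.05, below the 10% detection gate) and an
on-state mean of 2.0 in the sender/receiver types of the active regions:
SIRPA–CD47 (MG→OL) on in Control+NAWM, MIF→CD74 (OL→MG) on in CA+CI,
CSF1→CSF1R (OL→MG) on in NAWM only.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: batch effects and multi-dataset integration
(out of scope by design), ambient RNA and doublets, gene–gene correlation
beyond block programs, continuous differentiation trajectories (states are
discrete), donor-level variability beyond sampling noise, and realistic
transcriptome-wide mean/dispersion spectra. Recovery results show the
procedures are correct and calibrated under the planted model, not that
they would achieve the same accuracy on real snRNA-seq.

## Pipeline and reproducibility

`run_all` executes simulate → QC → normalize → cluster/annotate → train →
score → module-score → DA (each MS region vs Control) → communication →
DEG/ORA with one config and one seed. The global seed fans out to
per-stage seeds through a fixed `SeedSequence` spawn schedule, so stages
are individually re-runnable and two runs with the same seed are
byte-identical in every output (wall times live only in the manifest,
which also records SHA-256 checksums of all outputs). Default problem
sizes — 700 reference cells, 3,600 query cells, 2,000 genes, 1,000
permutations — keep a full run under a minute on one CPU while leaving
every planted effect comfortably detectable.

## Known limitations

- Per-neighborhood DA power is bounded by neighborhood size (see above).
- The softmax scores of cells from states absent from training are
  suppressed by the confidence-floor penalty rule but not guaranteed low;
  novelty detection beyond the `tau` threshold (e.g. conformal rejection)
  is out of scope.
- Dividing-OPC detection in adult queries is not guaranteed: the default
  query plants none, mirroring its near-absence in adult tissue.
- The permutation test shares one set of permutations across pairs within
  a region (standard practice); p-values across pairs are therefore
  correlated, which matters only for joint error statements, not per-pair
  validity.
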