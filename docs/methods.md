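# Methods

`cytotype` implements a profiling workflow for single-cell RNA-seq
abundance matrices (FPKM/TPM scale): gene pre-filtering, normalization,
hierarchical cell clustering with a permutation significance test,
per-cluster differential expression, cell-type enrichment and
marker-based validation, logistic-regression signature-gene ranking,
and cell-type-specific transcriptional-regulatory-network (TRN)
inference with a six-metric transcription-factor importance ranking.
This note records the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Data model and pre-filtering

The input is a genes × cells matrix of non-negative abundances with a
per-cell sample (preparation/batch) label. All values are floored at
0.01 so that logarithms and fold ratios are defined everywhere;
flooring is idempotent and is applied before any other step.

Pre-filtering combines two per-sample criteria, and a gene is retained
only if it passes both in **every** sample:

* **Expression filter** — gene *i* passes in sample *s* when at least
  *N* cells of *s* express it at ≥ θ (defaults θ = 5, N = 2, both in
  abundance units). Setting N = 1 retains genes carried by single,
  potentially rare, cells.
* **Cell specificity filter** — with x_ij the min–max scaled
  expression of gene *i* across the sample's *q* cells,
  τ_i = Σ_j (1 − x_ij)/(q − 1) ∈ [0, 1]. τ = 1 when exactly one cell
  expresses the gene and 0 for a perfectly flat gene (the scaling is
  0/0 there; we define τ = 0 since a flat gene is maximally
  unspecific). Default cutoff τ ≥ 0.7 per sample.

The report labels every gene with a section: 1 = passed both filters
everywhere (kept), 2 = expressed but unspecific, 3 = unexpressed,
4 = expressed in only part of the samples.

Two properties of τ on abundance-scale data are worth knowing. First,
τ decreases roughly as the fraction of expressing cells grows, so
signature genes of a population making up ≳ 35 % of the cohort can
fall under the 0.7 cutoff. Second, because abundance distributions are
right-skewed, even a uniformly expressed gene has τ well above 0; flat
housekeeping genes land near but not always below 0.7. Pre-filtering
therefore serves the clustering step; the differential-expression and
signature analyses operate on the full floored matrix so that genes of
large populations are still scored.

## Normalization and QC

Gene-level normalization is the per-sample z-score: each gene row is
centred and scaled within each sample (constant rows map to 0). It is
idempotent and removes multiplicative batch differences by
construction. Cell-level normalization scales every cell so its
trimmed mean (default 5 % per tail) equals the grand mean of all
cells' trimmed means. QC tables cover per-gene MA values
(M = log2 mean₁ − log2 mean₂, A their average), matched quantiles of
the two samples' per-gene means, and all cross-sample cell Pearson
correlations on log2(x + 1) with distance 1 − r. The exact
inter-sample correlation/distance convention was an open design point;
the log2(x + 1) scale was chosen for variance stabilization, and the
summary is diagnostic only.

## Clustering and cluster significance

Cells are clustered agglomeratively on centered-Pearson distance
d = 1 − r (range [0, 2]; the (1 − r)/2 scale is not used, so the
default cut height 0.5 lives on this conventional scale) with average
linkage. Three cutting rules are supported: a distance threshold
(default 0.5), a fixed number of clusters, or a scan of the merge
heights for the smallest cut leaving at most γ singletons (γ = 0 by
default). The threshold cut is the pipeline default: the γ-scan stops
at the first height where every cluster has ≥ 2 members, which on
noisy data can freeze an over-split partition of many small clusters;
it is most useful with visual inspection of the dendrogram. Cells are
sorted lexicographically before linkage so the partition is invariant
to input order, and clusters are labelled C1..Ck by decreasing size.

Cluster significance uses the coherence statistic T = (mean
within-cluster cell–cell Pearson correlation) − (mean between-cluster
correlation). The null permutes every gene's values across cells
independently (preserving gene marginals, destroying covariance),
re-clusters with identical settings, and recomputes T; when the null
partition degenerates (one cluster, or all singletons) a balanced
random bipartition is scored instead. Both a normal upper-tail
approximation (supporting extreme significance levels) and the
empirical (#null ≥ T + 1)/(B + 1) are reported, because the
approximation can claim far more extreme p than B permutations can
resolve.

## Differential expression

Each gene is tested one cluster versus the rest, one-tailed in the
"greater in cluster" direction, since downstream marker and signature
analyses concern over-expression. Welch's unequal-variance t-test is
used when both groups exceed `min_parametric_n` (default 5) cells;
otherwise the Wilcoxon rank-sum test, exact when the pooled sample is
≤ 20 with no ties, normal approximation with tie correction otherwise.
Benjamini–Hochberg adjustment is applied within each cluster's test
battery (the per-cluster family matches per-cluster reporting; a
global family is a one-line change). p-values are floored at 1e-300
before any −log transform.

## Cell-type matching

**Enrichment.** Each cluster's DE genes are tested for
over-representation in curated gene sets (GMT, or an association table
where a gene joins a cell type's set only with positive support at
p < 0.05 and no negative evidence) with a one-tailed Fisher exact
test; BH across cell types within a cluster; both raw-p ordering and q
are emitted. The default universe is the genes that survived
pre-filtering — the only genes eligible to be differentially
expressed.

**Marker validation.** Every marker of a panel ranks all N cells by
descending expression (average ranks on ties; absent markers are
dropped with a warning). Per cell, the robust-rank-aggregation score
is ρ = min_k P(X ≥ k), X ~ Binomial(m, r_(k)), over the cell's sorted
normalized ranks — small when the cell sits unexpectedly high in many
marker rankings. Only the ordering is consumed, so no multiplicity
correction is applied to ρ; a Borda (mean-rank) alternative is
selectable. The ROC AUC of the consensus ordering against the cluster
assignment (assigned cells = positives) is computed by the rank-sum
identity U/(n₊ n₋) with ties counting ½.

## Signature genes

Four features per (gene, cluster):

* **mc** ∈ {0,1}: expressed (≥ θ_expr, default 5 — the same abundance
  threshold as the expression filter, keeping one notion of
  "expressed" in the pipeline) in at least δ % of cluster cells
  (default 80; use 100 for highly uniform clusters);
* **mu** ∈ {0,1}: cluster mean ≥ α × (η-quantile of the gene outside
  the cluster), defaults α = 2, η = 0.85; the quantile tolerates a few
  outlier cells outside;
* **mt** ∈ [0,1]: −log p scaled by the cluster's maximum −log p;
* **ms** ∈ [0,1]: (1 + ρ)/2 with ρ the Pearson correlation between
  the gene's full-cohort profile and the cluster's idealized reference
  profile. The reference is the cluster indicator over **all** cells
  (1 inside, 0 outside): a reference restricted to the cluster's own
  cells could be constant and encodes nothing about selectivity,
  whereas the indicator expresses "on in this cluster, off elsewhere".
  Constant gene profiles get the neutral ms = 0.5.

A logistic regression of the label on (mc, mu, mt, ms) is trained on
known markers (positives) against an equal-sized seeded sample of
genes that are non-DE (p ≥ 0.05) and neither common nor unique
(negatives). A small ridge penalty (λ = 1e-4) keeps the
maximum-likelihood fit finite on separable training sets, which
marker-based positives frequently are. The fitted probability ranks
all candidate genes (the cluster's DE genes); a min–max normalized
score is reported alongside.

**Subsampling validation.** Per repetition: draw 80 % of the cluster's
cells, re-run the signature prediction on the subsample, take the top
`top_n` genes (default 100; the planted fixtures use 20 since they
carry 20 signature genes per population), and for every other cluster
train a linear support-vector classifier on 80 % of both clusters'
cells restricted to those genes (log2-transformed), scoring accuracy
on the held-out 20 %. Any linear margin classifier satisfies the
contract; the accuracy, not the classifier, is the deliverable. When a
subsample yields no DE candidates the repetition scores chance (0.5).

## Regulatory network and TF importance

Candidate TFs for a cluster are catalog genes (the TF/cofactor catalog
is a required user input; the fixtures bundle a synthetic one) either
differentially expressed (p < 0.05) or commonly expressed (mc = 1) in
the cluster; candidate targets are genes with p < 0.01.

For TF *i* and target *j*, every other candidate TF *k* is used as a
conditioner in the least-squares fit X_j = m + a X_i + b X_k + ε, and
the edge significance is S_ij = max_k p(a = 0), retained when
S_ij < 0.05. Taking the maximum makes the rule conservative: an edge
must survive its worst-case alternative explanation, so the null
retention rate is at most the cutoff. The coefficient test is the
standard two-sided t-test of a regression coefficient (the sign is
reported per edge). Conditioners nearly collinear with the tested TF
(|r| > 1 − 1e-10) are skipped; with fewer than three candidate TFs, or
all conditioners collinear, the marginal regression p is used.
Feedback from targets to TFs and self-loops are excluded.

Importance is computed on the undirected view of the main connected
component (the disruption metrics are defined through components and
mutual reachability; directionality is kept in the edge list). For
node *i* in a component of N nodes:

* DC = degree; CC = 1/Σ_j d_ij; BC = betweenness over ordered pairs,
  unnormalized (only ranks are consumed, and any consistent convention
  gives identical ranks);
* DFC = (#components after deleting *i*)/(N − 1);
* DCC = 1 − (#ordered residual pairs still mutually reachable)/((N − 1)(N − 2));
* DDC = 1 − (Σ ordered residual pairs 1/d)/((N − 1)(N − 2)), 1/∞ = 0.

TFs are ranked per metric in descending value with competition ranks —
tied elements share the numerically lowest rank of their block, the
convention that reproduces duplicate positions in a published-style
ranking table — and the final importance is the mean of the six ranks
(ties again share a position). Diagnostics report each metric's
sensitivity (mean tie-block size; 1 = fully resolving) and relative
power (Spearman correlation of the metric's ranking with the final
ranking, mean-normalized across the six metrics — a stand-in
concordance definition, as no canonical formula was available).

## Synthetic cohorts

The generator draws log-normal abundances: cell value =
2^(μ_g + N(0, σ)) × batch scale, with σ = 0.3 by default. Three
populations of 30/25/20 cells each carry 20 signature genes elevated
3 log2-fold over a baseline of 1 (log2 units); 30 housekeeping genes
sit at log2 = 5 everywhere; 50 noise genes at log2 = −2 fall to the
expression filter. Cells are assigned round-robin to two batches with
scale factors 1.0 and 1.5, so every batch contains every population
and the per-sample z-score has real work to do. The marker panel is
the first 5 signature genes per population; the association table maps
signatures to synthetic cell-type names with positive support
p = 0.01. Regulatory programs are planted separately: TF and decoy-TF
profiles are i.i.d. standard normal over one cluster's cells and each
target is coefficient × TF + N(0, 0.25) at 40 cells by default.

What the generator does **not** emulate: dropout/zero-inflation,
mean–variance count noise, doublets, cell-cycle structure, or
continuous differentiation trajectories. Passing tests therefore show
that the algorithms recover the structure they model — well-separated
discrete populations with multiplicative batch effects and linear
regulatory programs — not that they are robust to every artifact of
real single-cell data.

## Numerical choices and degenerate inputs

* z-scores are computed on the floored abundance scale (no implicit
  log); a log2(x + 1) pre-transform is a flag.
* Constant genes: τ = 0, z = 0, ms = 0.5. Constant cell vectors make
  the correlation distance undefined and raise an error naming the
  cell.
* Two-group tests on identical constant groups return p = 0.5 with a
  degenerate flag.
* Exact Wilcoxon switches to the tie-corrected normal approximation
  beyond pooled n = 20 or in the presence of ties.
* Agglomeration and all rankings break ties deterministically
  (lexicographic IDs, stable sorts), making every run bitwise
  reproducible under a fixed seed.

## Problem sizes

The bundled analyses run at deliberately small scale: the default
cohort is 75 cells × 140 genes, null calibrations use 5 000–10 000
genes and 500 simulated TF/target pairs, network recovery averages 20
seeded replicates at 40 cells, and subsampling validation uses 10
repetitions with 20-gene signatures. All sizes are configurable.
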