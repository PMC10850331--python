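# Methods

`somscape` implements an unsupervised workflow for bulk RNA-seq time courses
from stem-cell differentiation experiments, together with a synthetic data
generator that plants known structure so every stage can be scored against
ground truth. This note documents the models, the parameters that matter,
the numerical conventions, and what the synthetic benchmarks do and do not
demonstrate.

## Expression space

All analysis operates on gene-centred log2 fold changes
(Δe = e − ⟨e⟩ over all samples), derived from raw counts in four steps:

1. **Expression filter.** A gene is kept iff its CPM reaches
   `min_count / median(library size) × 10⁶` in at least *n* samples, *n*
   being the size of the smallest replicate class. Default `min_count = 10`.
   This is the plain CPM-threshold rule, deliberately without additional
   edge-case adjustments, so behaviour is exactly the documented formula.
2. **TMM normalization.** The reference sample is the one whose
   upper-quartile CPM is closest to the mean upper quartile. For each
   sample, genes with zero counts in either member of the pair are dropped;
   log2 expression ratios (M) are trimmed by 30% on each tail and average
   log2 abundances (A) by 5% on each tail (ranks are stable, ties broken by
   input order); the factor is 2 to the inverse-variance-weighted mean of
   the surviving M values, with delta-method weights
   `(N−y)/(Ny)` summed over the pair. Factors are rescaled to geometric
   mean 1. The implementation agrees with a brute-force sort-trim-average
   oracle to < 1e-9 and with the edgeR reference to ~1e-12 on probe
   matrices.
3. **logCPM.** `log2((y + p) / (Ñ + 2p) × 10⁶)` with effective library size
   Ñ = column sum × TMM factor and a fixed additive prior `p = 3`. A fixed
   prior (rather than a library-size-scaled one) keeps the transform an
   exact closed form that tests can verify directly.
4. **Gene centering.** Row means are subtracted over *all* samples
   (seeding samples included), making every downstream quantity a log2
   fold change against the gene's own grand mean. Replicate averaging to
   (protocol, day) condition means is a plain arithmetic mean.

## Sample hierarchy

Nine clustering variants — {euclidean, cosine, Pearson} × {single, average,
complete} — are built with SciPy's agglomerative linkage on condition
columns. Pearson distance is `1 − r`, cosine is `1 − cosine similarity`;
constant or zero sample vectors are rejected by name before these metrics
are applied.

**Lifetime cut.** With sorted merge heights d₁ ≤ … ≤ d₍ₙ₋₁₎, each flat
partition's lifetime is the gap to the next merge; the cut goes through the
largest gap, giving k = n − i clusters for the gap after the i-th height.
When no positive internal gap exists (two items, or all merges tied) the
1-cluster solution is returned. The implementation is checked against a
brute-force enumeration of all cut levels on random trees.

**Selection.** Partitions with k outside [2, n−1] are excluded. If one
partition is best on both the Silhouette coefficient (computed under the
partition's own metric) and the Calinski–Harabasz index (euclidean), it
wins; otherwise the minimum rank-sum over the two indices wins, ties broken
by higher silhouette and then variant order. The rule is deterministic and
respects both indices; disagreement is logged.

PCA operates on the sample × gene matrix via SVD with no scaling; because
rows are already centred across samples, column centering is a no-op and
variance fractions are exact ratios of squared singular values.

## Self-organising map

A square grid (default 40×40 — roughly one order of magnitude fewer nodes
than the 5000-gene default universe) is trained online for 3 epochs. Each
epoch presents every gene once in a seeded random order; the
euclidean-nearest node and a gaussian neighbourhood around it move toward
the gene. The learning schedule is a conventional linear decay — rate
0.5 → 0.05 and radius grid_side/2 → 1 over all steps — since nothing about
the application demands otherwise; everything is recorded in the config.
Nodes are initialised at randomly chosen genes plus gaussian jitter
(σ = 0.05), which stabilises the short 3-epoch training compared to pure
random initialisation.

After training, every gene is assigned to its nearest node, and each
occupied node's weight vector is replaced by the mean Δe profile of its
genes — the **metagene**. Empty nodes keep their trained weights (not NaN)
so portraits have no gaps; their occupancy is recorded as 0. Per-node
quality statistics: profile variance across samples, Shannon entropy over
10 equal-width bins spanning the node's own range (0 for constant
profiles), and the mean Pearson correlation between member genes and the
metagene.

A **portrait** is one sample's metagene grid min–max scaled to [0, 1]
(that sample's own range) and coloured blue → green → yellow → red. The
scaling is per-sample by design: portraits show each sample's internal
contrast, not absolute levels. Portraits are rendered for individual
samples and for replicate-averaged conditions; training on all individual
samples is the default, with condition means projected through the same
gene → node assignment.

## Grid segmentation and marker extraction

K-means (k-means++ seeding, 10 restarts, best inertia) partitions the
occupied node metagene profiles into 20 clusters labelled A…T by
descending size. Only occupied nodes participate; grid contiguity is
emergent, never enforced. A cluster is **significant** iff its mean profile
reaches |Δe| ≥ 1.0 (a two-fold change — the smallest conventionally
interesting effect; configurable) in at least one sample. The union of
genes on significant-cluster nodes is the unsupervised feature selection;
its adequacy is scored by re-clustering the condition matrix on the
selected genes alone and comparing lifetime partitions (adjusted Rand
index) and trees (cophenetic correlation).

Efficiency markers: among significant clusters, the one whose mean profile
is most negatively Pearson-correlated with replicate differentiation
efficiency across late samples (day ≥ 7 by default) is chosen — an explicit
statistic standing in for visual identification. Its genes are ranked by
peak Δe over all samples (ties broken by identifier) and the top 10
returned with their trajectories.

## Over-representation and bi-clustering

Over-representation of a gene list against a GMT collection is the
one-sided Fisher exact test in its hypergeometric upper-tail form
(`P(X ≥ overlap)`), verified against exhaustive enumeration of the pmf for
all universes up to 25 genes. Multiple testing uses Benjamini–Hochberg
across the collection (Bonferroni available). The universe must be given
explicitly — typically the post-filter gene list — since a whole-genome
background is not meaningful for synthetic data.

Bi-clustering builds two independent agglomerative hierarchies (euclidean,
complete linkage by default) on genes and samples, sharing the linkage
implementation with the sample-hierarchy module, and reorders the matrix by
both leaf orders. The heatmap uses a diverging scale symmetric about
0 Δe so values are comparable across samples, unlike the per-sample-scaled
portraits; column clustering can be disabled to keep experimental order.
Fixed-depth row cuts use the standard maxclust criterion; tied heights that
make a count unattainable produce the nearest attainable count with a
warning.

## Synthetic data generator

The generator emulates a two-protocol (2D monolayer vs 3D aggregate) hiPSC
cardiac differentiation time course: 2 protocols × 10 days
(0, 1, 3, 5, 7, 9, 12, 15, 18, 20) × 3 replicates, one condition (2D, day
12) in duplicate, plus 3 undifferentiated seeding samples — 62 samples.
Planted modules (piecewise-linear log2FC offsets over time; 50 genes each
by default):

- **pluripotency** — high in seeding samples and days ≤ 1, decaying by 5
  log2FC from day 0 to day 20;
- **transient mesoderm**, two sub-profiles — one peaking at day 3 and
  rapidly decaying (TBXT-like), one rising at day 3 and sustained
  (ROR2-like);
- **cardiac progenitor** — rising from day 7;
- **cardiomyocyte** — rising from day 9;
- **translation/ribosome** — expressed in seeding samples and 2D day 0,
  silent throughout the 3D protocol (2 log2FC, a moderate stemness-linked
  signal);
- **3D-only late maturation** — rising from day 15 in the 3D protocol;
- **endoderm contaminant** — 10 genes, active only in replicates with
  efficiency < 0.6, zero before day 7, peaking at 7 log2FC on day 9.

Per-replicate efficiencies default to constants spanning 0.45–0.90 (2D:
0.45/0.80/0.55; 3D: 0.75/0.90/0.70), so two of six replicates fall below
the contaminant gate — enough spread for the marker correlation while
keeping most replicates efficient.

Counts are negative binomial: per-gene relative means
`exp(baseline + ln 2 × Σ active offsets)` with baselines Normal(3, 1.2²) in
natural log, gene-wise dispersions log-uniform on [0.01, 0.5], and
library sizes log-normal around 10⁷ (σ = 0.3) to force non-trivial TMM
factors. The default universe is 5000 genes, a desk-scale stand-in for a
post-filter transcriptome; the 4640 non-module genes are independent noise.

**What passing means — and does not.** The generator reproduces the study's
*design* and the statistical structure the analysis assumes (overdispersed
counts, composition effects, stage-switch modules, a gated contaminant). It
does not reproduce real co-expression among "background" genes, real gene
identities, batch structure, or single-cell heterogeneity. Recovery results
on this benchmark therefore demonstrate the pipeline's correctness and
sensitivity under its own assumptions, not performance on any real dataset.
One known boundary case: the translation/ribosome module's 2-log2FC peak,
after node-level averaging with co-mapped background genes (~3 genes per
node at default scale), yields a cluster profile near the 1.0 significance
threshold, so that single module's selection is seed-dependent. The seven
stronger modules are recovered robustly.

## Problem sizes and determinism

Default analyses run at full study scale: 5000 genes × 62 samples, 40×40
grid, 3 epochs. The marker-recovery benchmark repeats the full
simulate-preprocess-SOM-segment-rank chain over 20 seeds. Unit and property
tests use smaller constructions (hundreds of genes, grids of side 5–12)
chosen to make each property sharp rather than to exercise scale.

All randomness funnels through one root seed; per-stage seeds are derived
by hashing `seed:stage`, and identical configuration yields byte-identical
summary output. Degenerate inputs are explicit errors (constant vectors
under correlation distances, zero-count libraries, empty selections,
constant efficiency) rather than silent NaNs.
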