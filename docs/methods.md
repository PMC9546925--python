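# Methods

This note records the statistical model behind each pipeline stage, the
parameters that matter, the design choices made where the procedure was
genuinely open, and what the synthetic benchmark does and does not show.

## Connectivity-significance expansion

The interactome is an undirected simple graph of gene symbols. Given a
seed set S₀ mapped into the network, each iteration scores every outside
node with at least one edge into the current module by the hypergeometric
upper tail P(X ≥ k_s) with population N (all network nodes), success count
s (current module size), and k draws (the node's degree). The minimal-p
node is admitted; p values across iterations are *not* comparable (s grows),
which is why a separate boundary criterion exists.

Choices:

- **Seed weight α** (default 1): links to original seeds can be counted α
  times, with N and s inflated by (α−1)|S₀|. The default reproduces plain
  counting, which is the procedure used throughout.
- **Tie-breaking** is unspecified in the expansion literature's common
  statement of the algorithm; we use larger k_s first, then lexicographic
  gene symbol, making rankings bit-reproducible.
- **k_s counts links to seeds plus previously admitted candidates** (the
  admitted candidate "is added to the set of seed nodes"); some variants
  count original seeds only.
- Tails are evaluated with `scipy.stats.hypergeom.sf` (log-space
  internals); the test suite checks exact agreement with rational
  enumeration for every parameter combination with N ≤ 25.

## Biological boundary

Seed-enriched annotation terms are found by the one-sided hypergeometric
over-representation test with BH adjustment; terms at adjusted p ≤ 0.05
(default) define the annotated ("true positive") universe as the union of
their genes. The sliding window at iteration t covers ranked positions
max(1, t−w+1)..t with w = |in-network seeds| by default; before the window
fills, a shrinking head window is used so the report starts at iteration 1.
The boundary is the *last* iteration with window enrichment p ≤ 0.01
(default) — the point where candidates with direct biological support
plateau; 0 when no iteration qualifies.

The enrichment background defaults to all interactome genes annotated in
the collection — the conservative, standard choice when the annotation
service's own background is unknown. Query genes outside the background
are dropped with a warning rather than counted.

## Batch correction

Parametric empirical-Bayes ComBat: per-gene standardization against the
grand mean and pooled variance, normal/inverse-gamma priors on per-batch
gene locations/scales fitted by method of moments, iterative conditional
shrinkage to convergence (1e-4), then removal of the shrunk effects. The
implementation reproduces the R/Bioconductor `sva::ComBat` output to
numerical precision (cross-checked in the tests on a small matrix).
`parametric_eb=False` switches to exact per-batch per-gene location-scale
standardization; this removes batch means exactly, whereas EB deliberately
leaves the shrunken sampling-noise component. A single batch passes
through unchanged; a one-sample batch is an error; zero-variance genes get
location-only adjustment with a warning.

Expression values are assumed to be log-scale intensities throughout
(`assume_log_scale`, default true); fold changes are differences of means
on that scale.

## Differential expression and the correlation network

Per-gene two-sided Welch t-test between case and control on log-scale
values, BH FDR across all genes; retained genes need FDR ≤ 0.001 and
linear fold change ≥ 1 (defaults). The threshold of 1 on the linear scale
is deliberately inert — with blood microarray intensities the retained
log fold changes are tiny (order 0.01–0.03) and the FDR carries the
filtering. The test itself is a choice: a plain Welch t is robust and
standard for two-group microarray contrasts; moderated-variance tests are
out of scope.

The correlation network is built over DEGs from the case samples only by
default (it is meant to be the *disease* co-expression network;
`correlation_samples` accepts "all"/"control"). The edge threshold is the
83rd percentile (default) of |Pearson r| over all unordered DEG pairs,
with linear interpolation on the sorted population so the threshold is
bit-reproducible; edges keep the signed r, and isolated genes are dropped.
If the percentile lands exactly on the maximum |r| (degenerate, e.g. all
pairs perfectly correlated) ties at the threshold are kept, otherwise the
inequality is strict. A connectivity profile (LCC fraction vs threshold)
is available for threshold diagnostics.

## Cartography and switch calling

Communities come from k-means on each node's vector of signed correlations
to all network nodes, with a fixed RNG seed. When k is not given it is
chosen by the elbow (maximum distance to the end-to-end chord) of the
inertia curve over k = 2..10. For every node: κ = edges inside its own
cluster, within-module degree z = (κ − mean_cluster κ)/sd_cluster κ
(population sd; z = 0 when the cluster is κ-degenerate), and clusterphobic
coefficient K_π = 1 − (κ/k)². Hubs are nodes with degree > 5; their APCC
is the mean signed r to their neighbours. Classes: fight-club (APCC < 0),
party (APCC ≥ 0.5), date (between). Switch genes: fight-club hubs with
K_π > 0.8 and z < 2.5. The APCC class boundary and the switch thresholds
follow the established switch-miner methodology; all are configurable.

Downstream filtering keeps switch genes matching a differential-expression
direction (default up) and, under the default "majority" rule, those in
the single cluster holding most of them (ties go to the smaller cluster
label; a named cluster can be forced via `cluster:<id>`).

## Module significance

For a gene set, the induced interactome subgraph is summarised by LCC
size, LCC edge count and total edge count. Null sets of the same size are
drawn without replacement within logarithmic degree bins (1, 2, 3–4, 5–8,
…, doubling), the standard matching for heavy-tailed interactome degree
distributions; exact-degree matching is available but easily infeasible on
small networks. Sampled sets may overlap the original set (an exclusion
flag exists, default off). Each metric is z-scored against its null
(default 1,000 draws) and reported with the one-sided upper-tail normal p
(the headline number) plus an add-one-smoothed empirical p; a degenerate
null (sd = 0) yields z = NaN and the empirical p only. The direction is
one-sided by construction: the question is whether the set is *more*
clustered than chance.

## Synthetic benchmark

The generator plants every structure the pipeline is designed to find, so
each stage can be scored against ground truth without external data.

- **Interactome**: Erdős–Rényi background at a fixed mean degree, or (the
  `broad` model) a Chung–Lu graph with log-uniform expected degrees over
  2–32 so that every doubling degree bin is populated — a property real
  interactomes have through their heavy tail and that degree-matched
  sampling needs. A planted module of 40 nodes is wired internally at
  density 0.3; its members draw modest background degrees (expected 2–8),
  because a disease module is locally dense through internal wiring, not
  because its members are global hubs.
- **Expression**: 800 genes × (100 case + 100 control) in 2 interleaved
  batches; log2-intensity baselines N(7, 1); three blocks of 100 genes
  sharing a latent factor with loading 2 at unit noise (within-block
  r ≈ 0.8); planted DEGs get a +2.0 case shift (about 2σ, chosen so the
  Welch test at n = 100/group recovers ≥95% at FDR 0.001); 10 connector
  genes carry the *negated* mean of all three block factors (scale 4), so
  their network neighbours span blocks and correlate negatively with them
  — APCC < 0, high K_π, low z by construction; additive per-gene batch
  shifts N(1.0, 0.5) on batch 2.
- **Bundle coherence**: the 15 seeds and the 10 connectors are all members
  of the planted interactome module, one GMT term covers the module
  (driving the boundary criterion), and 20 random decoy terms populate the
  background. With the default settings the structured correlation pairs
  make up ≈19% of all DEG pairs, so the 83rd-percentile threshold falls
  just inside the connector band (≈0.45–0.50) — block and connector edges
  survive, noise edges do not.

Problem sizes (500-node interactome, 800 genes, 120 expansion iterations,
1,000 randomizations) are scaled down from a full interactome study while
keeping every statistical mechanism active; the whole benchmark runs in
seconds.

What passing does **not** show: the generator is homoscedastic Gaussian
(a per-gene variance option exists), blocks are cleanly separated, batch
effects are purely additive, and annotation terms are noiseless. Real
microarray data have heavier tails, correlated noise, probe artifacts and
partially wrong annotations; recovery rates on real data will be lower,
and headline counts from any specific published analysis additionally
depend on the exact interactome, expression and annotation snapshots used
there.

## Numerical conventions and degenerate inputs

- Hypergeometric tails: P(X ≥ c) via `sf(c−1, ...)`; c = 0 returns 1
  exactly.
- BH adjustment through `statsmodels.stats.multitest`, verified against
  the step-up cumulative-minimum formula.
- Constant genes: undefined correlations are treated as 0; t-test NaNs
  become p = 1 (no evidence).
- k-means: `n_init=10`, fixed `random_state`; identical inputs give
  identical labels.
- Empty intersections, exhausted expansion frontiers and empty switch
  sets are warnings/empty results where the pipeline can continue, hard
  errors where a downstream stage would be meaningless (no seeds in the
  network, no seed-enriched term).

## Known limitations

- The boundary depends on the annotation collection; with a collection
  unrelated to the seeds the criterion is undefined (hard error) rather
  than silently unbounded.
- k-means on correlation profiles is sensitive to k; the elbow choice is
  a heuristic, and an explicit k should be preferred when the cluster
  structure is known.
- Degree-preserving sampling requires each occupied degree bin to hold
  enough nodes; on small or degree-homogeneous networks the test can be
  infeasible or the null degenerate (reported, not hidden).
- The normal-approximation p assumes an approximately Gaussian null;
  for small n_rep or discrete metrics the empirical p is the safer value.
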