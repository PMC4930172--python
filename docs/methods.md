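# Methods

This note documents the models, the synthetic study design, the numerical
choices, and the limitations of the `ffl_dynamics` package.

## Study design being emulated

The pipeline targets a staged case/control design: one control cohort without
time points and one case cohort profiled at three disease stages (acute,
subacute, chronic). Every per-stage contrast is cases-at-stage-s versus the
single shared control group; no longitudinal (paired) modeling is attempted,
matching the analysis style the pipeline reproduces. Regulatory inputs are
typed edge lists flattened from curated databases; the pipeline consumes them
as given and does not predict interactions.

## Preprocessing

Probes are kept when their maximum log₂ intensity over all samples is ≥ 7
("reaching" the threshold is read as inclusive; the threshold is
configurable). Probes mapping to two or more distinct gene symbols are
ambiguous and removed; unannotated probes are removed too, since they cannot
contribute to any gene row (the choice is ours — upstream descriptions are
silent on it). Remaining probes are averaged per gene (arithmetic mean of
log₂ values per sample), and only protein-coding genes are retained; a gene
with no biotype annotation is conservatively treated as non-coding and
logged. Each step is idempotent and the order is
filter → drop-ambiguous → collapse → keep-coding.

## Differential expression

The statistic is the classic empirical-Bayes moderated t. Per gene, a pooled
two-group variance s²_g with d_g = n₁ + n₂ − 2 df is shrunk toward a prior
variance s₀² with d₀ prior df:

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g)

(d₀, s₀²) are estimated by moment-matching the scaled-F distribution of s²_g
on the log scale (digamma/trigamma moment equations; the trigamma inverse is
solved by Newton iteration). p-values come from a t distribution on d_g + d₀
df; when the observed variances are effectively homogeneous the matched d₀ is
infinite, all posterior variances equal s₀² and the reference distribution is
normal. With d₀ = 0 ("ordinary" mode) the statistic reduces exactly to the
pooled-variance two-sample t. The implementation is cross-checked in the test
suite against the R `limma` reference (agreement ~1e-8 on t, p, and prior
df).

SDE calling uses BH-adjusted p < 0.001 **and** linear fold change
2^|Δ̄| > 1.2, both strict, direction-agnostic. Whether the 1.2 threshold is
linear or log-scale, strict or not, is underdetermined upstream; linear and
strict are this package's documented choices. Benjamini–Hochberg is the exact
step-up: q(i) = min_{k≥i} m·p(k)/k capped at 1, returned in input order.

Degenerate genes (zero variance everywhere, zero difference) get t = 0,
p = 1 rather than NaN.

Top-k ranking orders genes by minimum adjusted p across stages, ties broken
by larger maximum |log₂FC|, then lexicographic gene id — a total,
deterministic order.

## Profile clustering

Each gene's profile is (0, lfc₁, lfc₂, lfc₃): the control baseline followed
by per-stage mean log₂FC. Rows are standardized to mean 0, sd 1 (population
sd; constant rows are excluded with a warning). Whether the original analysis
standardized sample-level or stage-summary profiles is unknowable, so a
`samples` mode standardizing raw per-sample rows is exposed alongside the
default `stage-means` mode. Clustering is agglomerative with city-block
distance and complete linkage (scipy), cut at k = 2 by default; complete
linkage is monotone, so merge heights are non-decreasing. The per-cluster
pattern label (up-then-decay vs down-then-recover) is assigned by the sign of
the stage-1 cluster mean.

## Enrichment

Over-representation is the one-sided hypergeometric upper tail
P(X ≥ x) with universe N, set size K, draw n, overlap x — identical to a
one-sided Fisher exact test on the 2×2 table (verified to 1e-12 in tests).
The background universe is the set of genes surviving preprocessing, not the
whole genome: the draw (the SDE set) is a subset of analyzed genes, so any
larger universe would inflate significance. BH runs across all sets of a
collection per stage; significance is adjusted p < 0.05. When several
significant subpathways share a parent pathway, only the minimum-adjusted-p
one is kept (ties to the lexicographically smaller id). The stage × set
matrix distinguishes significant cells (the adjusted p), tested-but-not
significant ("ns"), and zero-overlap ("NA"), with an optional id filter
(e.g. removing cancer pathways).

## FFL motifs and networks

A co-regulatory motif is a miRNA m and TF t that regulate each other plus a
shared target g: edges m→t, t→m, m→g, t→g. Enumeration requires t and g to be
SDE; miRNAs are never expression-filtered because the design assumes no
matched miRNA profiles. A miRNA's target set includes its miRNA→TF edges — a
TF targeted by the miRNA is still a gene — so g may itself be a TF, and
g = t (TF self-regulation via a tf→tf self-loop) is allowed by default
(`allow_self_target`). Enumeration is index-based (hash joins over the typed
edge maps) and is verified against an exhaustive O(M·T·G) triple loop.

Merging the motifs of one stage unions their edges into a directed graph.
Edge labels: "inh" when the source is a miRNA (post-transcriptional
inhibition), "reg" when the source is a TF. A node's role is resolved from
its usage in the network: TF+gene iff it appears both in TF position and in
target position.

Degree has two conventions because mutual miRNA↔TF pairs make the directed
and collapsed counts genuinely different, and published per-type link totals
are not always reconcilable under a single convention. `collapsed` (default)
counts distinct neighbors in the undirected collapse (a self-loop adds 1);
`directed` counts incident directed edges (a self-loop adds 2). Both are
exposed and reported.

Betweenness centrality follows BC_i = Σ_{s≠i≠t} σ_i(s,t)/σ(s,t) summed over
*ordered* pairs, computed by Brandes accumulation (networkx). The formula as
written is direction-agnostic, so the default view is the undirected
collapse, where each unordered pair contributes twice (the path a–b–c gives
BC(b) = 2); a directed mode is available. The implementation is checked
against explicit geodesic enumeration on random graphs.

Hubs: the cited hub-calling method is not restated in the source material, so
the package's documented stand-in is degree ≥ the (1 − f) quantile of the
degree distribution (f = 0.20 by default), ties included — every network has
at least one hub.

## Cross-stage dynamics

Edge identity is (source, target, label), so an inhibition and a regulation
between the same endpoints are distinct — the same convention the network
comparison figures use. Venn decomposition assigns every node and edge to the
exact subset of stages containing it; regions are disjoint and sum to the
union (asserted in tests on every run). Transition regions are
exactly-{acute, subacute} and exactly-{subacute, chronic}; the
exactly-{acute, chronic} region is computed but carries no transition label.
Specific subnetworks are induced by a region's edges; endpoints whose own
region differs are flagged shared.

## Classification

Gaussian Naive Bayes with sample-frequency priors and per-class per-feature
normal densities, evaluated in log space. Class-conditional variances are
ML (ddof 0) with a floor of 1e-9 × the largest overall feature variance to
survive degenerate folds; the floor is fixed across LOOCV folds so fold
models are comparable. The positive-class posterior is the ROC score. LOOCV
is deterministic; a fold whose training half loses an entire class is scored
with the prior alone (warning logged). AUC uses the rank (Mann–Whitney)
formulation with tied scores counted ½, which equals trapezoidal integration
of the ROC sweep. Null calibration uses the standard permutation test —
scores held fixed, labels permuted — whose mean AUC is 0.5 by symmetry.
(Re-running LOOCV inside each permutation is a different estimator with a
known pessimistic bias below 0.5 and is not what the calibration checks.)

## Synthetic cohort: what it emulates, what it does not

Defaults mirror the emulated study scale: 2000 genes, 14 controls, 28 cases
per stage, 3 stages. Baselines are μ_g ~ Normal(10, 1.5²) on the log₂ scale,
with a 5% low-intensity fraction (μ ≈ 5) so the intensity-7 filter is
exercised; per-gene noise is Normal(0, 0.5²). 10% of genes are DE with
|log₂FC| = 1 and random fixed sign; the effect decays geometrically across
stages (factor 0.7), producing the acute > subacute > chronic SDE ordering
and the characteristic sharp-then-slow profile shapes. The probe-level
expansion adds duplicate probes with mean-zero offsets (collapse recovers
gene values exactly), multi-gene probes, unannotated probes and non-coding
genes for the filters to remove.

Planted FFLs pair miRNA i with TF i and target i; their TFs and targets are
forced into the DE pool, so the loops are enumerable at every stage where the
DE genes are recalled. Decoy edges are sampled uniformly over types and
role-consistent endpoints and rejection-sampled so no decoy completes an
unplanted loop among DE nodes; sampling is bounded at 100× the requested
decoy count and fails loudly if the constraint is unsatisfiable. Gene sets
draw 60% of planted-set members from the stage-1 DE pool; consecutive
subpathways share a parent pathway so the min-p collapse has work to do. The
biomarker pair is the TF and target of the first planted loop, shifted by
2 sd (stage-constant); recurrent cases get an extra 1 sd shift so the
recurrence task is non-degenerate.

What the generator does **not** emulate: probe-level microarray noise
structure (probe affinity, batch, background), correlated genes, miRNA
expression (none is generated, matching the design assumption), realistic
pathway topology, or patient-level longitudinal correlation (case samples at
different stages are independent draws). Passing recovery tests therefore
demonstrates correctness of the algorithms under the stated generative
model, not robustness to real microarray artifacts.

All generation is driven by `numpy.random.default_rng` seeded from the
config; identical (config, seed) produce byte-identical files. Distinct
substreams (seed, k) decouple expression, catalog, gene-set and probe
generation.

## Problem sizes in tests and the acceptance script

Unit and property tests run on desk-scale fixtures (hundreds of genes, ≤ 20
node graphs). The acceptance suite uses the stated study-condition sizes:
2000-gene null calibration over 200 replicates, 50 powered replicates at the
14-vs-28 design, 100 random catalogs for the motif oracle, 50 random graphs
for the betweenness oracle, and n = 200 panels for the classifier closed
form. The acceptance script reduces the null-calibration replicate count to
25 (its point estimate is stable far below the 0.05 bound) and reports every
other quantity at full scale. The complete suite runs in well under a minute
of CPU beyond the ~15 s acceptance tests.

## Known limitations

- The moderated-t prior fit assumes positive residual variances; genes with
  exactly zero variance are excluded from the moment fit (they still receive
  statistics via the degenerate-gene rule).
- `collapse_subpathways` treats rows without a parent id as their own
  parents (never collapsed together).
- The hub rule is a quantile stand-in for an unspecified published method;
  results depending on hub calls should be read with that in mind.
- The Venn decomposition is exact set algebra; it does not attempt any
  statistical assessment of overlap significance.
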