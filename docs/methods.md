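# Methods

## Scope and data model

`cernaforge` implements ceRNA-network inference for a two-group
(control vs case) expression study with three RNA classes profiled on the
same samples (mRNA, lncRNA, miRNA), plus externally supplied miRNA→target
prediction tables with pairing scores in [0, 1]. All expression values are
assumed to be on the log2 scale. Genes whose mean log2 abundance falls
below a floor are removed on read; the floor is configurable and defaults
to log2(4) = 2, i.e. transcripts averaging under four abundance units are
treated as unexpressed. Duplicate gene ids collapse to the row with the
larger mean (ties keep the earlier row), which makes re-reading written
matrices idempotent.

## Differential expression

Per gene, log2FC = mean(case) − mean(control) and a two-sample t test:
pooled-variance by default, Welch optional. A configurable variance floor
(default 1e-8) replaces zero pooled/per-group variance so that genes with
no within-group spread get a large finite t rather than an infinite one.
Benjamini–Hochberg q-values are always computed (via
`statsmodels.stats.multitest`); the DE gate is |log2FC| ≥ 1 together with
raw p < 0.05 by default, with a switch to gate on q instead. A moderated
(empirical-Bayes) t in the style of limma is deliberately **not**
implemented: the pipeline embodies the screening gates, not any particular
variance-shrinkage scheme, so genome-scale DE counts from studies analysed
with limma are not expected to be reproduced gene-for-gene.

## Triple network and ceRNA calling

The scaffold links DE miRNAs to their predicted targets, dropping
interactions with pairing score < 0.8. miRNAs with surviving targets in
both classes form the "bridge" subset; single-class miRNAs stay in the
graph but are flagged. Candidate (mRNA, lncRNA) pairs must be positively
co-expressed — signed Pearson r > 0.4 across shared samples, because ceRNA
co-regulation predicts positive correlation (an absolute-value gate is
available). Pairs involving a zero-variance profile are dropped with no
call rather than treated as errors. The correlation gate is applied before
the overlap test; the stages are independently callable so the order can
be rearranged by the caller if desired.

The overlap statistic for a surviving pair is the upper-tail
hypergeometric probability of sharing x miRNAs given K (mRNA-interacting),
N (lncRNA-interacting) and a universe of M miRNAs, evaluated with scipy's
log-gamma implementation (stable to M ~ 1e5). Two tail conventions exist
because published formulas are sometimes typeset with the sum running
through t = x (a strict tail, P(X > x)): the default is the inclusive
P(X ≥ x), which correctly assigns p = 1 to x = 0; the strict variant is
kept under `tail="as_printed"` for comparability.

Choice of M. The universe defaults to the miRNA node set of the triple
network (`M_policy="triple_network"`): that is the population from which
both partners' miRNA sets are actually drawn, and with it the test's null
rejection rate stays at or below nominal (the statistic is discrete, so
it is conservative at small K and N — rejection rates around 2% at
α = 0.05 are expected and verified in tests). Counting every miRNA in the
raw prediction tables (`total_mirnas_in_tables`) or supplying the
profiled-genome count (`user_supplied`, e.g. ~1000 profiled miRNAs)
enlarges M and makes the test anti-conservative relative to the sampling
process that generated the sets; both remain available because published
analyses typically use a genome-wide M. Pairs are called at raw p < 0.05
and x ≥ 1; no cross-pair multiplicity correction is applied by default
(a BH option exists). Each shared miRNA of a called pair is emitted as
one (mRNA, miRNA, lncRNA) triple; the expansion is lossless and is
verified as such.

## Topology fitness

Four per-node metrics on the simple undirected ceRNA graph:

- **degree** k;
- **topological coefficient** T(n) = mean_m J(n, m) / k(n) over nodes m
  sharing at least one neighbour with n, with J = shared-neighbour count
  plus 1 if n and m are adjacent; nodes with k ≤ 1 are assigned 0 and so
  drop out of fits (the NetworkAnalyzer convention — they have no
  neighbour-sharing tendency to measure);
- **closeness**: reachable-node count divided by summed shortest-path
  distances, i.e. component-local reciprocal mean distance (isolated
  nodes: 0);
- **betweenness**: exact Brandes accumulation, endpoints excluded,
  normalized by (V−1)(V−2)/2.

Each metric yields a series against degree and a power-law fit
y = a·x^b by OLS on (log10 x, log10 y); R² is reported in log space,
where the least squares is performed. Non-positive values are dropped
before the transform (required for it to exist); a series left with fewer
than 3 points refuses to fit and reports an error instead. A constant
series has zero residuals and reports R² = 1 with slope 0.

Two series conventions are implemented. The degree panel always fits the
degree distribution P(k). For the other three metrics the default
(`per_node`) fits the raw per-node (k, metric) scatter; the alternative
(`per_degree`) first averages the metric over nodes of equal degree. The
per-node convention is the default because it is what the Cytoscape
NetworkAnalyzer scatter plots fit, and on the packaged published network
it reproduces the reported R² values (0.827, 0.936, 0.690, 0.688) to
about three decimals, whereas degree-averaging smooths the scatter and
inflates R² (0.983/0.948/0.990 on the same graph). `validate` reports
both modes side by side with absolute deltas.

## Enrichment

ORA uses the same hypergeometric kernel (overlap of a hit list with a
gene set inside a stated universe, upper tail) with BH across sets. The
targeted GSEA ranks all other genes by Pearson correlation with a chosen
hub gene — appropriate when only expression, not phenotype labels per
permutation, is available — and scores a set by the weighted
Kolmogorov–Smirnov enrichment score: hits add |r|^p normalised by the
set's total weight (p = 1 by default), misses subtract 1/(n − n_set), ES
is the signed extremum of the running sum. If every hit metric is exactly
zero at p > 0, weights fall back to equal so the statistic stays defined.
Significance uses gene-label permutation: set labels are reassigned to
random ranking positions, p = (1 + #{|ES_perm| ≥ |ES_obs|}) / (1 + n_perm),
deterministic under the supplied seed. Phenotype permutation is not
offered because the ranking is single-gene correlation, not a per-sample
statistic. The packaged GMT ships three demonstration sets whose
*membership is synthetic* (the file and its descriptions say so); they
exist so examples and tests run, not as curated pathways.

## Synthetic data generator

The generator emulates the assumed study structure: two groups of 8
samples; log2 expression = per-gene baseline U(4, 10) + planted group
effect ± 1.5 for DE genes + shared latent factor + N(0, 0.5) noise. Each
planted triad pairs one DE mRNA with one DE lncRNA, gives both the same
effect sign, the same standard-normal per-sample latent factor scaled by
`latent_weight` (default 0.8), and a pool of 4 shared DE miRNAs whose
interaction scores are drawn U(0.8, 1). Background interactions appear
independently with probability 0.02 and U(0, 1) scores. All randomness
derives from one root seed through per-component `SeedSequence` spawns,
so identical seeds give byte-identical written datasets across platforms.

Default choices and why: `latent_weight = 0.8` puts the planted-pair
Pearson correlation around 0.85 (well above the 0.4 gate, satisfied in
>99% of planted pairs over replicates) while keeping within-group
variance low enough that the DE gate retains good power; unit weight
makes the latent factor dominate within-group variance and measurably
costs DE recall. Note that because ceRNA partners share their effect
sign, the group shift alone already induces positive correlation — so
pair recall is *not* monotone in `latent_weight` (a stronger factor helps
the correlation gate but hurts the DE gate); what the weight controls
monotonically is the induced correlation itself, and that is what the
property tests assert. Recall *is* monotone in the shared-pool size: a
single shared miRNA cannot reach p < 0.05 (its minimum attainable p is
1/M-scale), while four comfortably can.

What the generator does not emulate: count noise (a Gaussian log-scale
model is used, matching the linear-model assumptions of array-style
analyses), probe effects, batch effects, sample heterogeneity, or
cross-tissue discordance between the RNA classes. Passing recovery tests
therefore demonstrates the statistical machinery under the model's own
assumptions, not performance on real heterogeneous data.

Measured operating characteristics at the defaults (8v8, 300/150/80
genes, 10 triads — sizes chosen so the whole suite runs in seconds):
truth recovery averages recall ≈ 0.8 and precision ≈ 0.95 over seeds
1–5; under the null (no effects, no triads) the DE raw-p rejection rate
sits inside the 99% binomial CI of 0.05 and the hypergeometric rejection
rate is ≈ 0.02 (conservative, as expected for a discrete statistic).
These numbers are recomputed by the test suite, not quoted from
anywhere.

## Pipeline and determinism

Stages communicate through plain files (TSV, SIF, GraphML, GMT, YAML
config) so each intermediate is inspectable and each stage independently
invocable; the CLI (`cernaforge simulate|de|cerna|topology|enrich|
validate|run`) is a thin layer over the library. A run writes
`manifest.json` containing the config snapshot, per-stage status and a
SHA-256 digest of every artifact; identical config + seed reproduce
identical digests. A failing stage aborts the run, names itself in the
manifest (`status: failed`), and leaves prior artifacts flagged as
partial. Timestamps appear only in the run log, which is not hashed.

## Known limitations

- The hypergeometric test treats miRNA target sets as exchangeable
  uniform draws; real target predictions are strongly non-uniform, which
  the p-values do not model.
- The pooled t with a variance floor is not a shrinkage estimator; at
  n = 8 + 8 its power differs from moderated-t analyses.
- Exact reproduction of published R² values depends on the fitting
  convention of the original network-analysis tool; both plausible
  conventions are computed, and the one that matches is the documented
  default.
- The GSEA null permutes gene labels, which ignores inter-gene
  correlation; its p-values are calibrated per set, not family-wise.
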