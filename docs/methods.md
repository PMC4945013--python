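# Methods

This note documents the statistical procedures implemented in
`comorbevol`, the choices made where the design was genuinely open, and
what the synthetic test-bench does and does not establish.

## Presence/absence matrix and distances

Associations are reduced to unique (disorder, gene) pairs after symbol
normalization (uppercase, trimmed); the presence matrix orders rows and
columns lexicographically so it is invariant to input order. The
distance between two disorders is the binary (asymmetric Jaccard)
distance d = (b+c)/(a+b+c), where a counts genes present in both and
b, c genes present in exactly one; genes absent from both are ignored.
A pair with no genes at all is assigned d = 0 with a warning rather
than an error, since such rows can arise transiently in bootstrap
replicates.

## Ward.D2 clustering

Agglomeration uses the Ward.D2 criterion: the Lance–Williams update on
squared dissimilarities,
D(ij,k)² = [(nᵢ+nₖ)D(i,k)² + (nⱼ+nₖ)D(j,k)² − nₖD(i,j)²]/(nᵢ+nⱼ+nₖ),
with merge heights reported on the original (unsquared) scale. The
implementation is an explicit O(n³) agglomeration rather than a call
into a linkage library because bootstrap support requires a
*deterministic* tie-break — ties are common on binary distances — and
the documented rule is: among minimal-distance pairs, merge the
lexicographically smallest pair of cluster ids (leaves first, in label
order). Tests cross-check the merges against an independent
linkage implementation on tie-free data. The disorder count is small
(tens), so cubic cost is irrelevant even inside the bootstrap loop.

## Multiscale bootstrap (AU) support

Cluster identity across replicates is exact leaf-set equality. For each
scale r in the default grid {0.5, 0.6, …, 1.4}, the pipeline draws
`n_boot` (default 1000) resamples of round(r·n) gene columns with
replacement, re-clusters, and records BP(r), the fraction of replicate
trees containing the node's leaf set. Gene columns are the resampling
unit because they are the observations from which the disorder
dissimilarities are computed.

On the probit scale z(r) = Φ⁻¹(1 − BP(r)), the two-parameter model
z(r) = v·√r + c/√r is fitted by weighted least squares with weights
equal to inverse variances obtained by propagating the binomial
variance BP(1−BP)/n_boot through the probit transform. Then
AU = 1 − Φ(v − c), and its standard error follows from the WLS
covariance of (v, c) by the delta method:
se(AU) = φ(v−c)·√(Var v + Var c − 2Cov(v,c)). Proportions are clamped
to [1/(2·n_boot), 1 − 1/(2·n_boot)] before the transform. Nodes whose
leaf set appears in no (or every) replicate at every scale cannot be
fitted; they are pinned to AU = 0 (or 1) with zero standard error and
a `degenerate` flag, so every branch stays annotated. The headline BP
reported for a node is its proportion at the scale closest to r = 1;
a separately coded plain bootstrap verifies this proportion in tests.

Significant clusters are the maximal non-root nodes with
AU ≥ 1 − α (default α = 0.15). The root is excluded because it is
contained in every replicate tree by construction and would otherwise
always be the unique maximal significant node.

## Gene-set partition

Relative to a focal disorder and a disorder cluster containing it, the
five roles are: focal-only; focal genes shared only with in-cluster
disorders; focal genes shared with any out-of-cluster disorder; genes
of in-cluster disorders not in the focal set; and genes only of
out-of-cluster disorders. A focal gene shared with both in- and
out-of-cluster disorders defaults to the out-of-cluster role — the
outside-cluster contrast is the one that needs genuinely outside-shared
genes — and the tie rule is a flag (`shared_tie_rule`). Role sets are
disjoint by construction and checked on construction.

## Constrained fractions

Constrained elements carry per-element p-values and are filtered at
p ≤ 0.05 (threshold configurable). Filtered elements are merged into a
disjoint union per sequence before intersection, so overlapping or
abutting elements are never double-counted; a gene appearing in several
intervals contributes the union of its intervals as its footprint, and
"total length" is that footprint length as provided by the caller
(coding vs whole-gene footprints are the caller's choice). Coordinates
are BED: 0-based, half-open. The per-gene fraction is constrained
bases / footprint length. Set comparisons use the Mann–Whitney U test,
exact when min(n) ≤ 8 with no pooled ties and otherwise the normal
approximation with midrank tie correction and continuity; two-sided by
default, with one-sided alternatives available.

## pN/pS ratio of means and its resampling null

For a gene set S, the statistic is mean(pN over S)/mean(pS over S) —
equivalently sum(pN)/sum(pS) — a set-level intensity of non-synonymous
relative to synonymous polymorphism. To test whether a small set's
ratio is elevated relative to a larger comparison set, B (default
1000) subsets of size |small| are drawn from the large set without
replacement (a with-replacement flag exists), the ratio is computed for
each, and p = #{null ratio ≥ observed}/B. Ties count as extreme, so the
p-value is conservative and never exactly 0; an observed ratio beyond
every resample is displayed as "< 1/B". The tail is upper by default
(the working hypothesis is an elevated focal-only ratio) and
configurable. A "sum over threshold / sum of all values" reading of the
tail would not yield a probability, so the count-based tail fraction is
used. Genes missing from the statistics table are dropped with logged
counts.

The four panel contrasts compare: (A) focal-only vs all shared focal
genes; (B) focal-only vs shared-within-cluster; (C) focal-only plus
shared-within-cluster vs shared-outside; (D) focal-only vs
shared-outside. The side carrying the elevated-ratio hypothesis is
listed first; when it is the larger side, the smaller side is resampled
against it and the tail flips to "lower", so every panel tests the same
direction regardless of which side is size-matched.

The null is approximate rather than exact: the small set is not pooled
into the resampling population, and subsets of the large set have
slightly smaller variance than an independent sample of the same size
(finite-population effect), so the type-I error at nominal 0.05 sits
slightly above 0.05 (measured ≈ 0.064–0.072 under a matched null at
n = 100/1000, B = 200). The tie rule pushes the other way. This is the
procedure as specified; callers needing exact exchangeability can pool
the sets themselves before calling.

## Pathway coverage and degrees

A pathway's coverage for a KO set is 100·|hit KOs|/|total KOs|, with
totals taken from the snapshot's declared pathway sizes. A pathway
counts as "involved" in a disorder when at least one KO of the
disorder's genes maps to it (threshold 1); unique-to-focal pathways are
those involved in the focal set and in no other disorder's. Degree
reports are sorted with id tie-breaks, and the handshake identity
(ΣKO degrees = Σpathway degrees = #edges) is asserted on every run.
KEGG content is consumed exclusively as an offline three-table
snapshot; coverage numbers are snapshot-version dependent by nature.

## Synthetic generator

Defaults (chosen once as the reference study conditions): 6 disorders
in two blocks of three, 400 genes, within/between-block sharing
probability 0.8/0.05, focal-unique fraction 0.25 and focal-shared
fraction 0.35, ω = E[pN]/E[pS] of 0.35 for focal-only vs 0.25 for all
shared roles, constrained-base density 0.4 (focal-only) vs 0.6
(shared), dN/dS lognormal with a +0.4 log-shift for focal-only genes
(σ_log = 0.5), gene lengths lognormal (median 1 kb, σ_log = 0.5,
floor 90 bp), pS = max(1, Poisson(length/200)), pN | pS =
Poisson(ω·pS). The pS floor keeps per-gene ratios defined; the
analysis itself uses set-level means. Each gene gets one significant
constrained element sized to its role's density (Gaussian placement
noise, σ = 0.05) and, with probability 0.5, a decoy element with
p > 0.05 that the significance filter must remove. Truth roles are the
roles *realized* by the drawn membership pattern relative to the block
containing the focal disorder, so exact recovery by the partition
stage is well defined. All draws come from per-stage generators spawned
from the config seed; identical configs produce byte-identical files.

What the generator does not emulate: literature-mining noise and
citation bias in the associations, linkage between neighbouring genes,
length- or GC-dependent ascertainment of polymorphisms, overlapping
genes, and real KEGG topology. Passing the planted-truth tests
therefore demonstrates that the statistics detect effects of the
assumed form at realistic sizes — not that the literature-derived
inputs are unbiased.

## Problem sizes in the test-bench

The planted-truth acceptance check runs the full pipeline on 50
independent seeds of the default configuration (n_boot = 1000,
B = 1000) and requires at least 80% of runs to recover both planted
blocks at AU > 0.85, the focal-only set exactly, and all three
contrasts directionally at p < 0.05 (measured: 98%). Null calibration
uses 500 runs at n = 100/1000 with B = 200. Module tests use smaller
replicate counts; `scripts/acceptance.py` re-runs the reference
conditions end-to-end from a single command-line seed.

## Known limitations

- AU p-values are reported raw, per branch; no multiplicity adjustment
  across nodes is applied.
- The WLS curve fit is a least-squares approximation to the maximum
  likelihood fit of the scaling model; with 1000 replicates per scale
  the difference is well inside the reported standard errors.
- The resampling null's mild anticonservatism (above) matters most for
  p-values near the threshold; the headline planted effects are far
  from it.
- Gene symbols are matched by normalized string equality only; no
  alias resolution is attempted.
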