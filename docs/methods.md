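# Methods

## Overview

`gebvnet` implements a network-based strategy for nominating putative
regulators of quantitative phenotypes from transcriptome data. Its central
idea is to treat genomic estimated breeding values (GEBVs) — per-sample
additive genetic merit estimates for each trait — as first-class nodes in a
co-expression network, so that "feature associated with phenotype" becomes
"feature–trait edge survives the partial-correlation test". Candidate
features attached to at least one trait are then ranked by GEBV-targeted
regulatory impact factors (RIF) computed between contrasting sample groups,
and the resulting annotation layers (RIF significance, hubs, differential
expression, transcription factors, eQTL evidence, pathway membership) drive
successive network rounds that narrow a transcriptome down to a small
regulator candidate set.

## The PCIT edge test

For every unordered pair of nodes (x, y) and every third node z, the
first-order partial correlation is

    r_xy.z = (r_xy − r_xz·r_yz) / sqrt((1 − r_xz²)(1 − r_yz²))

and the trio's tolerance is the average ratio of partial to direct
correlation,

    ε_xyz = (1/3)·(r_xy.z / r_xy + r_xz.y / r_xz + r_yz.x / r_yz).

Node z locally rejects the edge (x, y) iff

    |r_xy| ≤ |ε_xyz · r_xz|   and   |r_xy| ≤ |ε_xyz · r_yz|,

and an edge is *significant* iff no third node rejects it. There is no
p-value thresholding anywhere; the tolerance test is the only filter.

Degenerate cases are handled conservatively and identically in the
vectorized implementation and the brute-force reference used in tests:

* a ratio term whose direct correlation is exactly 0 is dropped from the
  tolerance mean; a trio whose three direct correlations are all 0 rejects
  nothing;
* a trio containing a perfect correlation (|r| ≥ 1 − 1e-12) is skipped —
  the partial correlations are undefined there — and any perfect edge is
  reported significant;
* an edge with r exactly 0 is never significant;
* constant (zero-variance) nodes are dropped with a logged warning before
  correlation.

The implementation loops over the conditioning node z and evaluates all
pairs against that z with dense matrix arithmetic, so the O(n³) trio scan
costs O(n²) memory; the expression trees match the scalar formulas exactly,
which makes the vectorized decisions bit-identical to the naive triple loop
(asserted over random instances in the test suite). A node-subset option
restricts the analysis to a named subset. At the package's reference scale
(1,110 nodes × 113 samples) one PCIT run takes on the order of a minute on
one core; the full trio scan is cubic, so transcriptome-scale runs
(>10,000 nodes) should use the subset option or substantial compute.

Pearson correlation is used throughout, matching the algorithm's
definition; a rank-transform toggle (Spearman-style) exists but is off by
default. Correlation is location/scale invariant, so whether GEBV columns
are standardized beforehand does not affect any decision.

### What the tolerance test can and cannot remove

Two structural properties matter when interpreting results:

* **Mediated edges survive when links are strong.** For a chain
  x ← z → y with link correlations c (so r_xy = c²), the population
  tolerance is ε = (2/3)/sqrt(1 + c²) — the tested edge's own ratio term is
  exactly zero — and the mediated edge is rejected iff c ≤ 1/sqrt(3) ≈
  0.577. Above that, the tolerance is too small relative to the links and
  the indirect edge is kept. The package's chain fixtures therefore use
  links around r ≈ 0.41 (noise sd 2.2 on unit-variance mediators), inside
  the rejection regime; even there, sampling noise at n = 100 leaves the
  observed single-trio rejection rate near 80–85%, not 100%.
* **Sampling-noise edges are not removable.** The test removes edges that a
  third variable explains; a spurious correlation arising purely from
  sampling noise has no explaining variable, so null pairs in the upper
  tail of the sampling distribution (|r| ≳ 0.25 at n = 113) survive. At the
  reference scale ~3–4% of null feature–trait pairs pass. Specificity
  improves with the size of the conditioning pool, so small node sets
  retain proportionally more noise edges. Users who need high precision
  should combine the edge list with an explicit |r| floor; the package
  deliberately does not impose one.

## Contrast groups and the PCA sample score

Per-trait contrast groups are the `group_size` (default 15) samples with
the largest and smallest GEBV for that trait; ties are broken by sample id
so selection is deterministic, and a degenerate all-equal trait logs a
warning.

For the all-traits analysis each sample receives a score

    A_i = Σ_j w_j · (Z_i · v_j),

where Z is the column-standardized GEBV matrix (population sd), v_j the
j-th eigenvector of the trait correlation matrix, and w_j the fraction of
variance explained by component j (a switch allows the raw eigenvalue
instead). This is a variance-fraction-weighted sum of the sample's
principal-component scores. Eigenvector signs are fixed by making each
component's largest-magnitude loading positive, so scores are reproducible
across linear-algebra backends. Scores are invariant to positive affine
rescaling of any trait column. If every trait column is constant the
standardized matrix is identically zero and all scores are defined as 0;
if only some columns are constant, standardization is undefined and the
call errors.

## RIF with GEBV targets

For candidate i and target trait j, with high/low group means ē_j^H, ē_j^L
of the trait's GEBV, a_j = (ē_j^H + ē_j^L)/2, d_j = ē_j^H − ē_j^L, and
within-group Pearson correlations r_ij^H, r_ij^L between candidate
expression and the trait GEBV:

    RIF1_i = (1/n_t) Σ_j a_j · d_j · (r_ij^H − r_ij^L)²
    RIF2_i = (1/n_t) Σ_j (ē_j^H · r_ij^H)² − (ē_j^L · r_ij^L)²

This transcribes the classical regulatory-impact-factor structure with
GEBVs substituted for differentially expressed target abundances: RIF1
rewards abundance-weighted differential wiring, RIF2 rewards differential
ability to predict the target. Raw scores are z-standardized across
candidates (population sd; the z columns have mean 0 and sd 1 exactly) and
a candidate is significant when |z| ≥ 1.96 on either score — the cutoff is
inclusive and the two scores confer significance independently.

Design notes:

* Swapping the high and low groups negates both raw scores and leaves
  significance calls unchanged.
* A candidate constant within a group contributes r = 0 with a logged
  warning; fewer than two candidates make z-standardization undefined
  (error from the model; the per-trait/overall wrappers degrade to an empty
  table with a warning instead so pipelines keep running).
* With centered GEBV targets a_j ≈ 0, so the RIF1 weight a_j·d_j is small;
  for a single target this is a common factor across candidates and the
  z ranking is unaffected (it reduces to ranking by differential wiring).
* **Rank stability at small groups.** With 15-sample groups the sampling sd
  of a within-group correlation is ≈ 1/sqrt(12) ≈ 0.29, so a null
  candidate's differential wiring |r^H − r^L| reaches ≈ 0.9–1.1 somewhere
  among ~50 candidates in most datasets. A genuine regulator that is wired
  in one condition and silent in the other (dw ≈ 1) therefore tops the
  RIF1 ranking only ~50–65% of the time, although it is almost always
  *significant* (|z| ≥ 1.96, observed ≈ 96% of seeds). Only sign-switching
  regulators (dw ≈ 2) are reliably rank-one at this group size. RIF output
  should be read as a significance screen, not a total order.

## Pipeline

Stage order: low-expression filter (optional; a feature must have count > 0
in ≥ `min_samples` samples, default 22, genes and miRNAs filtered
separately) → PCIT over genes + miRNAs + traits ("general") → PCIT over
miRNAs + traits ("miRNA", giving the sparse miRNA layer a run not dominated
by genes) → union of feature–trait edges from both runs (records carry
their source run; features found in both are flagged) → per-trait RIF and
the PCA-score overall RIF → attribute-annotated association network with
hub detection → per-trait expression-only PCIT over correlated features ∪
that trait's DEGs (skipped with a notice when no DEG annotations are
supplied) → selection of edges touching a hub or RIF-significant node → a
final PCIT round over the selected elements (pathway members, hubs, TFs,
miRNAs, RIF-significant features), with edges incident to RIF-significant
nodes marked.

Hubs are nodes whose degree strictly exceeds the mean plus twice the
population standard deviation of the degree sequence of the network under
analysis (so uniform-degree networks have no hubs); the multiplier is
configurable. Degrees count only the significant edges of that network.

Functional enrichment is an input/output contract point: the pipeline
exports candidate lists and accepts pathway-membership lists; it never
computes enrichment. Normalization (VST) and batch correction are likewise
upstream concerns — the pipeline takes pre-normalized matrices, with
`log_scale` (log2(count + pseudocount)) provided only so synthetic count
data can flow end-to-end.

Every run writes its resolved configuration and a JSON manifest with
per-stage outputs, parameters and input checksums; a rerun whose inputs
checksum-match resumes past the PCIT stages (the expensive ones) by
reloading their edge tables. With a fixed config and seed, two clean runs
are byte-identical in all data outputs; the run log carries wall-clock
timestamps and is excluded from that guarantee.

Defaults: `min_samples` 22 (a ≈ 20%-of-cohort alternative is provided),
`group_size` 15, RIF cutoff |z| ≥ 1.96, hub multiplier 2, PCA weight
"proportion".

## Synthetic data

The generator emulates the structure of a multi-trait livestock muscle
study; defaults are 113 samples, 1,000 genes, 100 miRNAs and 10 traits.

* **GEBVs** are multivariate normal. The first 6 traits form a correlated
  block generated by a one-factor loading structure with loadings evenly
  spaced in [0.88, 0.985], giving pairwise correlations in [0.77, 0.97]
  (positive semi-definite by construction); remaining traits are
  independent, mimicking a mineral-type trait that segregates apart from
  the rest.
* **Planted associations** (default 20) are features following
  β·Z(GEBV_trait) + N(0, σ²) with β = 0.75 against unit noise, i.e.
  population r = β/sqrt(β² + σ²) = 0.6. Features and traits are chosen by
  the seeded generator; the rest of the expression matrix is independent
  Gaussian noise.
* **Planted regulators** (default 1) follow the standardized sum of the
  block-trait GEBVs in the high-scoring half of the samples (β = 2 against
  sd-0.5 noise) and are pure noise in the other half — differential
  co-expression by construction. The "high half" is defined by the
  generator-side score so PCA-score contrast selection can be validated
  against recorded truth.
* **Counts** for filter tests are zero-inflated negative binomial with a
  configurable structural-zero fraction.

All outputs are byte-deterministic under (config, seed); each stage draws
from its own seed stream so adding features never perturbs other stages.
What the generator does **not** emulate: count-based mean–variance
structure in the expression used for networks (Gaussian, since PCIT/RIF
operate on normalized expression), co-expression modules among background
genes, batch effects, or pedigree structure in the GEBVs. Passing tests
demonstrate algorithmic correctness and recovery power under these
idealized conditions, not performance on real transcriptomes — in real
data, correlated backgrounds both help PCIT (larger conditioning pool) and
hurt it (indirect edges), and the clean planted/null separation does not
exist.

## Verification scale

The test suite verifies exact properties on fixtures and oracle agreement
on small random instances, and runs the full pipeline once at the reference
scale (113 × 1,110 × 10; about 1.5 minutes end-to-end on one core).
Multi-seed power properties are measured at reduced feature counts chosen
so the whole suite completes in a few minutes; `scripts/acceptance.py`
re-measures everything from scratch, including the full-scale run, at the
conditions listed above.
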