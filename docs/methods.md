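# Methods

This note documents the models, conventions and numerical choices behind
`ptrubric`, and what its synthetic tests do and do not demonstrate.

## The similarity metric

The unit of analysis is a publication type or study design (PT) — e.g.
*Randomized Controlled Trial*, *Cohort Studies*, *Editorial*. A multi-label
tagger assigns every article a probability in (0, 1) for each of 72 PTs.
The similarity between two PTs is the Spearman rank correlation ρ between
their probability columns across a common article set: rank each column
(average ranks on ties), then take the Pearson correlation of the ranks.
Being rank-based, ρ ignores score calibration and measures only how
consistently two PTs order the literature. With 72 PTs there are
72·71/2 = 2556 unordered pairs; summaries (min/max/mean, 40-bin histogram on
[−1, 1]) are computed over the strict upper triangle so each pair counts
once. Summary statistics are reported to 3 decimals.

A constant probability column has zero rank variance, so its correlations
are undefined; the package treats this as a hard error rather than emitting
NaN, because a NaN would silently corrupt the downstream clustering.

## From correlations to a rubric

Correlations are converted to dissimilarities with d = 1 − ρ, the standard
correlation distance, mapping [−1, 1] monotonically onto [0, 2]. The
PT × PT distance matrix is clustered agglomeratively under the Ward
criterion using the Lance–Williams recurrence on the squared distances as
given:

d²(k, i∪j) = [(nᵢ+nₖ)·d²(k,i) + (nⱼ+nₖ)·d²(k,j) − nₖ·d²(i,j)] / (nᵢ+nⱼ+nₖ)

No Euclidean embedding is attempted; merge heights are the square roots of
the merged d² values. Because the input is generally non-Euclidean,
height inversions are possible and are not treated as errors. The
implementation is in-package (O(n³) but trivial at n = 72) rather than
delegated, because the stability protocol needs a documented, deterministic
tie rule: ties in the merge criterion are broken toward the
lexicographically smallest pair of cluster indices under the current input
order. `scipy.cluster.hierarchy.linkage` serves as an independent
cross-check in the test suite.

Cutting the tree by undoing the last k−1 merges yields flat clusters; the
two rubric levels come from cuts at k_low = 13 and k_broad = 5 of the same
tree, which makes nesting (every low-level category inside exactly one
broad category) structural rather than empirical. One PT — *Scientific
Integrity Review*, far too rare in realistic corpora for a stable
correlation estimate — is excluded from clustering and merged back by an
explicit manual placement (`with:Retraction of Publication`, i.e. it joins
the scholarly-publishing/integrity cluster) and flagged as manual.

## Stability protocol

Robustness of the extracted structure is probed two ways at once:

* **multiplicative perturbation** — each off-diagonal correlation is
  independently multiplied by a factor drawn uniformly from
  {1−x, 1, 1+x}, mirrored for symmetry and clamped to [−1, 1]; zero
  correlations are fixed points. x runs over 0.010…0.025 in steps of
  0.001 (16 values).
* **order shuffling** — the PT list is randomly permuted before clustering
  and neighbour extraction, exercising the tie rule above; results are
  mapped back to the original label space before comparison.

Every perturbation repetition is crossed with every shuffle:
n_reps × n_shuffles combined runs per x (2000 × 100 = 200 000 under the
defaults), with the x loop outside that product. The headline statistic is
per-PT nearest-neighbour retention — the fraction of runs in which a PT's
most-correlated partner is unchanged (neighbour ties break
lexicographically by name). Flat-cluster membership retention at a chosen
cut is additionally reported when requested, but is not the pass
criterion. All randomness derives from one master seed through
per-(x, repetition, shuffle) substreams, so reports are bit-reproducible
and independent of execution order.

A small design point: "well-separated blocks" test fixtures use 2-member
blocks. With three or more members at an identical within-block
correlation the nearest neighbour is exactly tied, and perfect retention
under perturbation is not a theorem; with 2-member blocks it is (a 0.9
within-pair correlation perturbed by ≤2.5% cannot drop below a ~0 cross
correlation inflated by ≤2.5%).

## The unified hierarchy

The hierarchy is a DAG over 90 nodes: 5 broad rubric categories (the
roots), 13 low-level rubric categories, and 72 PT terms. Multiple parents
are supported — MeSH itself is polyhierarchical — and the shipped fixture
uses them: every PT term has its low-level rubric category as one parent,
and MeSH-style placements add PT→PT edges (the trial subtypes under
*Clinical Trial*, the observational designs under *Observational Study*,
both of those plus *Clinical Trial Protocol*, *Retrospective Studies* and
*Prospective Studies* directly under *Clinical Study*). Two deliberate
encoding choices, recorded in the fixture's changelog block: *Randomized
Controlled Trial* sits directly under *Clinical Trial* (the placement under
*Controlled Clinical Trial* is left as a variant), and retrospective/
prospective designs hang off *Clinical Study* rather than any single
observational design, since such articles can be interventional or
observational.

Two closure operations drive applications:

* `expand_query(t)` = {t} ∪ descendants(t), restricted to PT terms by
  default — PubMed-style automatic query expansion.
* `normalize_tags(T)` = T ∪ {PT-term ancestors of every t ∈ T} —
  post-prediction normalization, making binary indexing
  hierarchy-consistent (anything tagged *Cohort Studies* is also tagged
  *Observational Study* and *Clinical Study* regardless of those raw
  scores). Both are monotone and idempotent; rubric categories are never
  emitted by default because they are organizational, not indexing targets.

## Threshold selection

Per-PT binary decisions use the threshold maximizing F1 on a validation
set, searched over the midpoints between adjacent distinct sorted scores
plus sentinels below the minimum and above the maximum — a finite grid
covering every achievable confusion table. Tagging uses strict `>` at the
threshold. F1 ties resolve to the largest qualifying threshold, favouring
precision. Thresholds are fit on raw scores only; hierarchy normalization
runs strictly after thresholding and never feeds back. When every
validation label is positive the search degenerates gracefully (any
threshold below the minimum score gives F1 = 1, and one is returned);
a column with no positives is an error because F1 is undefined.

## Synthetic data generator

The generator emulates the *statistical* structure of tagger output so the
whole pipeline can be tested against a planted truth. Articles are drawn
from a Gaussian copula: a latent multivariate normal whose correlation
matrix is the planted target pre-warped by r = 2·sin(π·ρ_S/6) — the inverse
of the Gaussian/Spearman relation ρ_S = (6/π)·arcsin(r/2) — then pushed
through a logistic function shifted to each PT's base rate. The monotone
push-forward leaves ranks untouched, so the sample's Spearman structure
converges to the stated Spearman targets, which is the scale the pipeline
measures. Targets that are not positive semidefinite are refused with the
offending eigenvalue; silent repair would change the planted truth.

The canned `fig2like` scenario plants the 13 rubric blocks over the real
72-term vocabulary with a within-block Spearman target of 0.6 (a stand-in
location for the positive mode of real pooled correlations, which the
source data only fix loosely), zero background across blocks, two
negatively correlated category pairs (general clinical/observational
studies vs. biographical works at −0.45; trial methodology vs. commentary
at −0.3 — emulating functionally unrelated PTs), and a base rate of 0.15
(PT indexing is sparse). Its pooled correlation histogram is bimodal with
one mode near 0 and one near the within-block target, and the full
pipeline recovers the planted partition at k = 13 with adjusted Rand
index ≥ 0.95 at n = 5000 articles.

What the generator does **not** emulate: article text and metadata, the
most-specific-term-only behaviour of human indexers, calibration artifacts
of a real model, heavy-tailed prevalence differences between PTs, or the
exact numeric values of the published correlation matrix. Tests passing on
synthetic data therefore certify the pipeline's correctness and stability
properties, not any empirical claim about the real literature.

## Problem sizes and determinism

Default analysis sizes are those of the target application (72 PTs, 2556
pairs, 2000 × 100 stability runs per x). The test suite and the acceptance
script exercise the same code paths at reduced sizes chosen to keep the
whole suite fast while leaving every property decidable: n = 5000 articles
for copula/recovery checks (sampling error on ρ is ~0.014 there), 20 × 10
or 25 × 4 run grids for the stability protocol (retention 1.0 on separated
blocks is exact, not asymptotic, so small grids lose nothing), 5–9-leaf
matrices for the clustering oracles. Every stochastic test and script is
seeded; reports are bit-identical across reruns with the same seed.

## Reference data

The published 72×72 PT Spearman matrix is distributed as supplementary
material of the source study and is not bundled here. Checks that need it
(`tests/test_acceptance.py::test_published_matrix_*`) expect a copy at
`src/ptrubric/data/reference/pt_spearman_72x72.csv` and fail until one is
supplied; all other tests are self-contained. The synthetic stand-in
produced by `synthetic_reference_matrix()` reproduces the structural
features the pipeline relies on, never the published values.

## Known limitations

* Ward-on-precomputed-distances is a convention, not the only reading of
  "correlations inverted to distances"; other transforms (e.g. 1 − |ρ| or
  √(2(1−ρ))) would change the tree. The package fixes d = 1 − ρ and the
  Lance–Williams update as documented.
* `cut` undoes the last k−1 merges; in the presence of height inversions
  this is the merge-order cut, which can differ from a height-threshold cut.
* The hierarchy fixture resolves the flattened printed form of the source
  tables; genuinely ambiguous placements are encoded one way and logged in
  the fixture changelog rather than silently guessed.
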