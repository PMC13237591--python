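# ptrubric

Tools for organizing biomedical **publication types and study designs**
(collectively, PTs — *Randomized Controlled Trial*, *Cohort Studies*,
*Case Reports*, *Editorial*, …) in a data-driven way. MeSH scatters these
terms over several independent trees, and tree position says little about
how similar two PTs actually are. `ptrubric` is aimed at people building or
evaluating automated PT indexing pipelines and at curators maintaining
PT vocabularies. It provides:

* a **similarity metric**: Spearman rank correlation ρ between the
  per-article probability columns of two PTs, computed from the output of a
  multi-label tagger over a shared article set (72 PTs → a 72×72 matrix of
  2556 pairwise correlations);
* a **rubric**: correlations are converted to distances (d = 1 − ρ) and
  clustered with Ward linkage via the Lance–Williams recurrence; cutting
  the tree at k = 13 and k = 5 gives nested low-level and broad categories;
* a **stability protocol**: each correlation is multiplied by a factor from
  {1−x, 1, 1+x} for x = 1%…2.5% and the PT order is shuffled, crossing
  2000 repetitions with 100 shuffles per x (200 000 combined runs), to test
  whether each PT's nearest neighbour survives;
* a **unified hierarchy**: a validated DAG of all 72 PT terms and the
  rubric categories, with PubMed-style query expansion
  (`expand_query`) and post-prediction tag normalization
  (`normalize_tags`);
* **prediction utilities**: per-PT F1-optimal thresholds, strict-`>`
  thresholding, and hierarchy-consistent normalization of binary tags;
* a **synthetic generator** (Gaussian copula with pre-warped Spearman
  targets) that plants known block structure, so every stage is testable
  without real model output.

## Worked example

```python
import ptrubric as pt

# a synthetic stand-in for the 72-PT correlation matrix: 13 planted blocks
# matching the shipped rubric, generated from a seeded Gaussian copula
S, truth = pt.synthetic_reference_matrix(seed=1)

print(pt.summarize(S).rounded())
print(pt.nearest_neighbour(S, "Case Series"))

rubric = pt.build_rubric(
    pt.to_distance(S), k_low=13, k_broad=5,
    manual={"Scientific Integrity Review": "with:Retraction of Publication"},
    exclude=("Scientific Integrity Review",),
)
print(len(rubric.low_categories()), len(rubric.broad_categories()))
print(rubric.low["Case Reports"] == rubric.low["Case Series"])

h = pt.load_default_hierarchy()
print(sorted(h.normalize_tags({"Cohort Studies"})))
```

prints

```
{'min': -0.472, 'max': 0.62, 'mean': 0.034, 'n_pairs': 2556}
Case Reports
13 5
True
['Clinical Study', 'Cohort Studies', 'Observational Study']
```

Reading the output: the 2556 pooled pairwise correlations range from
strongly negative (planted "functionally unrelated" category pairs) through
a mode near 0 (unrelated PTs) to a positive mode near the planted
within-block value; *Case Series*' most-correlated partner is
*Case Reports*; clustering the 71 non-excluded PTs and merging the one
manual placement back in yields 13 low-level categories nested in 5 broad
ones, with the two case-based PTs sharing a category; and normalizing the
tag set {*Cohort Studies*} adds its PT-term ancestors, so indexing is
hierarchy-consistent regardless of the ancestors' own scores.

The same stages are available from the shell:

```
ptrubric simulate --scenario fig2like --n-articles 5000 --seed 1 --out probs.csv
ptrubric similarity --probs probs.csv --out simdir/
ptrubric cluster --corr simdir/correlation_matrix.csv --k-low 13 --k-broad 5 --out clustdir/
ptrubric stability --corr simdir/correlation_matrix.csv --reps 20 --shuffles 10 --seed 1 --out stabdir/
ptrubric hierarchy expand --term "Clinical Study"
ptrubric run --config config.json     # end-to-end with a manifest
```

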