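# cellrules

Qualitative cell-type biomarkers and quantitative classification rules from
labeled single-cell expression matrices.

Given a cells × genes matrix of normalized expression (log2(TPM+1) scale)
with a class tag per cell — e.g. the tissue × cell-type labels of a
metastatic lung adenocarcinoma single-cell atlas with 32 classes ranging
from 159 to 19,478 cells — the package answers two questions: *which genes
identify each cell type* and *which threshold rules separate the types*.

## The pipeline

1. **Class-size filter** — keep cell types with strictly more than 100 cells.
2. **Boruta** — all-relevant feature selection: each gene races permuted
   "shadow" copies of the features inside a random forest; hits against the
   best shadow are tested with a two-sided binomial test (fair-coin null,
   Bonferroni over undecided genes) to confirm or reject genes.
3. **mRMR (MID)** — survivors are ranked greedily by
   `MI(g, y) − (1/|S|) Σ_{s∈S} MI(g, s)` on three-state (μ ± σ) discretized
   expression, i.e. relevance to the label minus mean redundancy with
   already-ranked genes (mutual information in bits).
4. **Incremental feature selection** — prefixes of the ranked list (step 10)
   are each scored by 10-fold stratified cross-validation of a CART or
   random-forest classifier; training folds are SMOTE-balanced
   (`c = a + r(b − a)` interpolation between same-class nearest neighbors)
   so minority cell types are not drowned out. Performance is the
   multi-class Matthews correlation coefficient in covariance form:
   `MCC = cov(X,Y) / √(cov(X,X)·cov(Y,Y))` over the N × K one-hot prediction
   and truth matrices (1 = perfect, 0 = random, −1 = complete opposition).
5. **Rules** — a CART/Gini tree on the optimum gene set is unrolled into one
   root-to-leaf rule per leaf; genes occurring in only one class's rules are
   reported as class-exclusive biomarker candidates.
6. **Enrichment** — one-sided hypergeometric over-representation of a
   selected gene list against user-supplied gene sets (GMT), threshold
   p < 0.001.

A seeded synthetic-data generator with planted marker structure
(`cellrules.synth`) makes every stage testable offline with ground truth.

## Worked example

```python
from cellrules import (SyntheticConfig, generate, run_boruta, discretize,
                       rank_mrmr, run_ifs, find_optimum, ClassifierSpec)

ds, truth = generate(SyntheticConfig(seed=1))   # 300 cells x 115 genes,
                                                # 15 planted markers
res = run_boruta(ds, seed=1)
print(len(res.important))                       # -> 15 (all planted markers)

sub = ds.subset_genes(res.important)
ranked = rank_mrmr(discretize(sub), sub.labels)
curve = run_ifs(ds, ranked, ClassifierSpec("random_forest"), seed=1)
print(find_optimum(curve))                      # -> (10, 1.0)
```

On this benchmark Boruta recovers exactly the 15 planted markers from 100
noise genes, and the forest reaches MCC 1.0 with the first 10-gene prefix:
the planted structure is fully recoverable. The `examples/` directory has
one narrative script per capability (simulation, feature selection, IFS,
rules, enrichment); each prints the numbers it computes and what they mean.

A thin CLI mirrors the stages for shell use:

```sh
cellrules simulate --seed 1 --out sim
cellrules run-all --synthetic --seed 1 --outdir run1
```

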