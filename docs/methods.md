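# Methods

## Scope and data model

The package operates on a `LabeledDataset`: a cells × genes matrix of
non-negative, already-normalized expression values (log2(TPM+1) scale) with
one class tag per cell. No re-normalization, gene filtering, or upstream
scRNA-seq processing is performed; all genes are passed to Boruta, which is
responsible for rejecting uninformative (including constant) genes. The
class-size filter keeps classes with *strictly* more than `min_cells`
(default 100) cells — a class of exactly 100 cells is dropped. The matrix
orientation is cells (rows) × genes (columns) everywhere.

Dense matrices are read and written as delimited text (header row of gene
ids, first column of cell ids; delimiter sniffed), sparse ones as
matrix-market triplets with one-id-per-line sidecar files. The dense writer
uses full repr precision, so write-then-read round-trips values
bit-identically.

## Boruta (all-relevant selection)

Each iteration: copy every active gene into a shadow column, permute each
shadow independently, fit a random forest (100 Gini trees by default) on
originals + shadows, and credit a hit to every original whose mean-impurity
importance exceeds the *maximum* shadow importance. After each iteration
every undecided gene's hit count is tested against Binomial(n_iter, ½),
two-sided, at `alpha` (0.05) Bonferroni-corrected over the currently
undecided genes; significantly many hits confirms, significantly few
rejects and removes. Confirmed genes stay in subsequent forests (they keep
competing and shape shadow importances), rejected ones leave.

The natural stopping rule is "no gene undecided"; on data with noise genes
that state is reached quickly, but a loop conditioned on *all* genes being
confirmed could never terminate, so `max_iter` (100) is the hard stop and
the leftovers are "tentative". Only "important" genes are passed
downstream. With Bonferroni over ~100 genes at α = 0.05, roughly 13
unanimous iterations are needed before the first decision, so `max_iter`
below ~20 leaves everything tentative.

One seeded generator drives both the permutations and the per-iteration
forest seeds, making reruns bit-identical.

## mRMR ranking (MID variant)

Expression is discretized per gene into three states around the gene's own
moments: below μ − σ → −1, above μ + σ → +1, else 0 (a constant gene is all
zeros). Mutual information is the plug-in estimator on the empirical
contingency table, reported in bits; the base only scales scores and never
changes the ranking.

Ranking is greedy forward selection under the difference (MID) criterion:
the first pick maximizes MI(g, y); each later pick maximizes
MI(g, y) − (1/|S|) Σ_{s∈S} MI(g, s). The mean-redundancy form is the
standard greedy surrogate for the set-level objective with the 1/|S|²
double sum; step by step the two choose identical genes. Ties break by
input gene order, implemented as "first gene within 1e−12 of the maximal
criterion" so that mathematically tied genes are not ordered by
floating-point summation noise. The pairwise MI sweep is evaluated as a
batched one-hot contingency product, which keeps the O(G²) ranking fast at
test scales; its values agree with independent per-pair counting to
1e−12 (tested).

## SMOTE and cross-validation

Minority classes are filled up to the majority size by interpolation:
pick a random class member *a*, one of its k = 5 nearest same-class
neighbors *b* (Euclidean; distance ties broken by cell index order; k
capped at class size − 1), and emit c = a + r(b − a), r ~ U(0, 1). Being a
convex combination, a synthetic cell lies coordinate-wise inside its
parents' bounding box and inherits non-negativity. Parents and r are
recorded per synthetic cell, so the interpolation identity is directly
checkable. A singleton class has no neighbor and is an error.

Cross-validation is stratified 10-fold — with many classes and minority
sizes near 100, unstratified folds can lose classes entirely — and the
held-out predictions of all folds are pooled into a single MCC/accuracy
record rather than averaged per fold. By default SMOTE runs *inside* each
training fold ("within"), never touching held-out cells. Balancing the
whole dataset before splitting ("before") is available as an explicit
fidelity option, because interpolated cells then share parents across the
train/test boundary and scores become optimistic; the test suite verifies
that on pure-noise data the "within" default keeps the IFS optimum MCC
below 0.2. Per-class accuracy is within-class recall; overall accuracy is
pooled; the degenerate single-class MCC is defined as 0.

## Incremental feature selection

Prefixes of the ranked list are evaluated at sizes step, 2·step, …
(step 10), plus a final prefix with all genes when the total is not a step
multiple. Each prefix is scored independently with the harness above; the
optimum is the row with maximal MCC, ties to the smaller prefix. Classifier
defaults are pinned: CART with Gini and no depth cap; random forest with
100 Gini trees and √G feature sampling. Subsets are evaluated serially;
results are identical under any parallel schedule because every evaluation
seeds its own folds.

## Rules and exclusive genes

The rule tree is a CART/Gini tree grown to purity (min_samples_leaf = 1, no
depth cap) on the *original, unbalanced* dataset restricted to the optimum
gene set. Each leaf yields one rule: the root-to-leaf sequence of
(gene, ≤/> , threshold) tests, the leaf's majority class, its training
support and purity. By construction the rules partition the training cells:
every cell satisfies exactly one conjunction and supports sum to N.

A gene is *exclusive* to a class when it occurs in at least one rule
predicting that class and in none predicting another; occurrence is counted
by gene (either relation). One structural caveat matters: in a tree grown
to purity on cells that are pairwise distinct in the selected gene space,
every internal node has pure leaves of at least two classes beneath it (a
pure node is never split), so *every* path gene occurs in several classes'
rules and the strict report is empty. Non-empty strict reports arise only
when leaves can be impure — duplicated expression vectors in large sparse
matrices, or an explicit `min_samples_leaf > 1`. For continuous data the
package therefore also offers `positive_only=True` (count a gene only where
it appears with the ">" relation, i.e. where elevated expression argues for
the class — the usual marker-gene reading) and `min_support` triage; on the
synthetic benchmark the positive-only report attributes planted private
markers to their own classes.

## Enrichment

Over-representation is the one-sided hypergeometric upper tail
P(X ≥ k) with universe N, term size K, selection n, overlap k, computed
with `scipy.stats.hypergeom`. The universe is an explicit input (gene-set
GMT files plus the caller's gene background); selected genes outside it are
dropped with a warning. No hierarchy-aware decorrelation is attempted, and
no multiple-testing correction is applied by default (raw p < 0.001), with
Benjamini–Hochberg available as an option.

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes:
baseline expression Normal(μ₀ = 1, sd 0.5) rectified at zero on the log
scale, identically across classes; marker genes shifted +`effect_size`
(default 2 log units) in their owning class — private markers in exactly
one class, "shared" markers additionally in the cyclically next class so
they discriminate without being exclusive; dropout zeroing each entry with
probability 0.1 after the shift; imbalanced class sizes (200, 50, 50 by
default, echoing the two-orders-of-magnitude spread of real cell-type
tables). Gene names encode the truth (`noise_0007`, `pv_B_03`, `mk_A_01`),
and the in-class minus out-of-class mean of a private marker converges to
`effect_size · (1 − dropout_rate)`.

It deliberately does *not* model library-size variation, batch effects,
gene–gene correlation beyond the planted shifts, or negative-binomial
counts. Passing tests therefore demonstrate that the machinery recovers
planted additive signal under dropout and imbalance — not that it is robust
to every artifact of real scRNA-seq data.

## Problem sizes and determinism

The test battery and examples use 300-cell, ~115-gene datasets (five seeds
for recovery claims), where the full pipeline runs in minutes on one CPU;
all stages scale to larger inputs without code changes. Every stochastic
component (generator, Boruta, SMOTE, fold shuffling, classifiers) consumes
an explicit seed; the pipeline derives per-stage seeds from one global seed
by hashing the stage name, and reruns are byte-identical, which the suite
checks.

## Known limitations

- Boruta's binomial test is two-sided with Bonferroni; other corrections
  (e.g. Benjamini–Hochberg, as in some Boruta variants) are not offered.
- The discretization scheme is fixed at μ ± σ; quantile or adaptive
  binning is out of scope.
- Strict exclusive-gene reports are empty for purity-grown trees on
  distinct cells (see above); use the relaxed counting options or impure
  leaves for practical marker triage.
- The IFS curve evaluates nested prefixes only; non-nested subset search is
  out of scope.
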