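"""All-relevant feature selection by the shadow-attribute scheme.

Each iteration copies every still-undecided (or confirmed) gene into a
shadow column, permutes each shadow independently to break its association
with the class label, fits a random forest on originals + shadows, and
records a "hit" for every original gene whose Gini importance exceeds the
maximum shadow importance. Hit counts are then tested against a fair-coin
binomial null (two-sided, Bonferroni-corrected over the currently undecided
genes): significantly many hits confirms a gene as important, significantly
few rejects and removes it. Genes still undecided when the iteration budget
runs out are tentative; only important genes are passed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestClassifier

from cellrules.datamodel import LabeledDataset

IMPORTANT = "important"
TENTATIVE = "tentative"
REJECTED = "rejected"


@dataclass
class BorutaResult:
    """Per-gene outcome of the shadow-feature loop."""

    status: dict = field(default_factory=dict)
    hit_counts: dict = field(default_factory=dict)
    n_iterations: int = 0

    def genes_with_status(self, status: str) -> list:
        return [g for g, s in self.status.items() if s == status]

    @property
    def important(self) -> list:
        return self.genes_with_status(IMPORTANT)

    def to_frame(self) -> pd.DataFrame:
        genes = list(self.status)
        return pd.DataFrame({
            "gene_id": genes,
            "status": [self.status[g] for g in genes],
            "hit_count": [self.hit_counts[g] for g in genes],
        })

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def run_boruta(ds: LabeledDataset, max_iter: int = 100, alpha: float = 0.05,
               seed: int = 0, n_trees: int = 100) -> BorutaResult:
    """Run the shadow-attribute loop on a labeled dataset.

    Parameters
    ----------
    ds
        Labeled dataset with at least 2 classes and 5 cells.
    max_iter
        Iteration budget; genes undecided at exhaustion are tentative.
    alpha
        Familywise significance level for the binomial hit test
        (Bonferroni-corrected over currently undecided genes).
    seed
        Seeds one generator that drives both shadow permutations and the
        per-iteration forests, so reruns are bit-identical.
    n_trees
        Trees per iteration forest; importance is mean Gini decrease.
    """
    if ds.n_cells < 5:
        raise ValueError("need at least 5 cells")
    if len(ds.classes) < 2:
        raise ValueError("need at least 2 classes")
    if ds.n_genes < 1:
        raise ValueError("need at least 1 gene")

    rng = np.random.default_rng(seed)
    y = ds.labels.astype(str)
    genes = list(ds.gene_ids)
    status = {g: TENTATIVE for g in genes}
    hits = {g: 0 for g in genes}
    # confirmed genes stay in the forest; rejected ones are removed
    active = list(genes)
    n_iter = 0

    while n_iter < max_iter and any(s == TENTATIVE for s in status.values()):
        n_iter += 1
        idx = ds.gene_index(active)
        X = ds.matrix[:, idx]
        shadows = X.copy()
        for j in range(shadows.shape[1]):
            rng.shuffle(shadows[:, j])
        Xall = np.hstack([X, shadows])
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        ).fit(Xall, y)
        imp = rf.feature_importances_
        shadow_max = imp[len(active):].max()
        for j, g in enumerate(active):
            if imp[j] > shadow_max:
                hits[g] += 1

        undecided = [g for g in active if status[g] == TENTATIVE]
        thr = alpha / max(len(undecided), 1)
        for g in undecided:
            p = binomtest(hits[g], n_iter, 0.5, alternative="two-sided").pvalue
            if p < thr:
                status[g] = IMPORTANT if hits[g] > n_iter / 2 else REJECTED
        active = [g for g in active if status[g] != REJECTED]

    return BorutaResult(status=status, hit_counts=hits, n_iterations=n_iter)
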