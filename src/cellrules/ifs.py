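"""Incremental feature selection over prefixes of the mRMR-ranked gene list.

Gene subsets grow in steps of 10 (prefix sizes 10, 20, ...; a final prefix
with all genes if the total is not a multiple of the step). Each prefix is
scored by stratified cross-validation of a CART or random-forest classifier,
and the optimum is the prefix with maximal multi-class MCC (ties to the
smaller prefix).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from cellrules.datamodel import LabeledDataset
from cellrules.metrics import EvalRecord, cross_validate
from cellrules.mrmr import RankedGeneList


@dataclass
class ClassifierSpec:
    """Which classifier to evaluate and its pinned hyperparameters.

    CART always splits on Gini impurity and is grown without a depth cap;
    the forest uses 100 Gini trees with sqrt-feature sampling.
    """

    name: str = "random_forest"
    n_trees: int = 100

    def validate(self) -> None:
        if self.name not in ("cart", "random_forest"):
            raise ValueError(f"unknown classifier: {self.name!r}")


def make_classifier(spec: ClassifierSpec, seed: int = 0):
    """Instantiate the sklearn estimator for a spec with a fixed seed."""
    spec.validate()
    if spec.name == "cart":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    return RandomForestClassifier(
        n_estimators=spec.n_trees, criterion="gini", max_features="sqrt",
        random_state=seed, n_jobs=1,
    )


@dataclass
class IFSCurve:
    """Per-prefix-size evaluation records for one classifier."""

    rows: list = field(default_factory=list)   # (n_features, EvalRecord)
    classifier_name: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def mcc_at(self, n_features: int) -> float:
        for n, rec in self.rows:
            if n == n_features:
                return rec.mcc
        raise KeyError(f"no curve row at n_features={n_features}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_features": [n for n, _ in self.rows],
            "mcc": [r.mcc for _, r in self.rows],
            "overall_accuracy": [r.overall_accuracy for _, r in self.rows],
        })

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None):
        """MCC (y) versus number of genes (x)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.to_frame()
        ax.plot(df["n_features"], df["mcc"], marker="o", label=self.classifier_name)
        ax.set_xlabel("number of features (genes)")
        ax.set_ylabel("MCC")
        ax.legend()
        return ax


def build_subsets(ranked: RankedGeneList, step: int = 10) -> list:
    """Prefix gene lists of sizes step, 2*step, ..., plus a final all-gene
    prefix when the total is not a step multiple."""
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(ranked)
    if n == 0:
        raise ValueError("ranked list is empty")
    sizes = list(range(step, n + 1, step))
    if not sizes or sizes[-1] != n:
        sizes.append(n)
    return [ranked.top(s) for s in sizes]


def run_ifs(ds: LabeledDataset, ranked: RankedGeneList, spec: ClassifierSpec,
            step: int = 10, folds: int = 10, smote_policy: str = "within",
            smote_k: int = 5, seed: int = 0) -> IFSCurve:
    """Evaluate every ranked-list prefix with cross_validate."""
    spec.validate()
    curve = IFSCurve(classifier_name=spec.name)
    for genes in build_subsets(ranked, step):
        rec = cross_validate(ds, genes, spec, folds=folds,
                             smote_policy=smote_policy, smote_k=smote_k,
                             seed=seed)
        curve.rows.append((len(genes), rec))
    return curve


def find_optimum(curve: IFSCurve) -> tuple[int, float]:
    """The (n_features, MCC) row with maximal MCC; ties to fewer features."""
    if not curve.rows:
        raise ValueError("empty curve")
    best_n, best_mcc = curve.rows[0][0], curve.rows[0][1].mcc
    for n, rec in curve.rows[1:]:
        if rec.mcc > best_mcc:
            best_n, best_mcc = n, rec.mcc
    return best_n, best_mcc
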