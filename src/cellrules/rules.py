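"""Decision-rule extraction from a CART tree and exclusive-gene reporting.

A CART/Gini tree grown to purity on the optimum gene set yields one rule per
leaf: the root-to-leaf conjunction of threshold tests, the leaf's majority
class, its training support and purity. A gene is "exclusive" to a class
when it appears in at least one rule predicting that class and in no rule
predicting any other class — the qualitative biomarker notion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from cellrules.datamodel import LabeledDataset


@dataclass
class DecisionRule:
    """One root-to-leaf path: ordered (gene, relation, threshold) tests."""

    conditions: list            # (gene_id, "<=" or ">", threshold)
    predicted_class: str
    support: int
    purity: float

    def matches(self, row: np.ndarray, gene_pos: dict) -> bool:
        """Does an expression vector satisfy every condition?"""
        for gene, rel, thr in self.conditions:
            v = row[gene_pos[gene]]
            if rel == "<=":
                if not v <= thr:
                    return False
            elif not v > thr:
                return False
        return True

    def condition_string(self) -> str:
        if not self.conditions:
            return "(always)"
        return " AND ".join(f"{g} {r} {t:.4f}" for g, r, t in self.conditions)


def train_rule_tree(ds: LabeledDataset, genes, seed: int = 0,
                    min_samples_leaf: int = 1) -> DecisionTreeClassifier:
    """Grow a CART/Gini tree on the dataset restricted to ``genes``.

    The default (min_samples_leaf=1, no depth cap) grows to purity. A larger
    leaf size stops early, leaving impure majority-vote leaves — useful when
    purity rules are too fragmented to interpret.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene subset")
    sub = ds.subset_genes(genes)
    tree = DecisionTreeClassifier(criterion="gini", random_state=seed,
                                  min_samples_leaf=min_samples_leaf)
    tree.fit(sub.matrix, sub.labels.astype(str))
    tree.gene_ids_ = list(genes)  # remember column -> gene mapping
    return tree


def extract_rules(tree: DecisionTreeClassifier) -> list[DecisionRule]:
    """One DecisionRule per leaf, conditions in root-to-leaf order."""
    if not hasattr(tree, "tree_"):
        raise ValueError("tree is not fitted")
    t = tree.tree_
    genes = getattr(tree, "gene_ids_", None)
    if genes is None:
        genes = [f"x{i}" for i in range(t.n_features)]
    classes = tree.classes_

    rules: list[DecisionRule] = []

    def walk(node: int, path: list) -> None:
        if t.children_left[node] == -1:  # leaf
            support = int(round(t.weighted_n_node_samples[node]))
            k = int(np.argmax(t.value[node][0]))
            purity = float(t.value[node][0][k] / t.value[node][0].sum())
            rules.append(DecisionRule(list(path), str(classes[k]), support, purity))
            return
        g = genes[t.feature[node]]
        thr = float(t.threshold[node])
        walk(t.children_left[node], path + [(g, "<=", thr)])
        walk(t.children_right[node], path + [(g, ">", thr)])

    walk(0, [])
    return rules


@dataclass
class ExclusiveGeneReport:
    """class tag -> genes occurring only in that class's rules."""

    mapping: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        recs = [(c, g) for c in sorted(self.mapping) for g in sorted(self.mapping[c])]
        return pd.DataFrame(recs, columns=["class", "gene_id"])

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def exclusive_genes(rules: list[DecisionRule], min_support: int = 0,
                    positive_only: bool = False) -> ExclusiveGeneReport:
    """Genes appearing in rules of exactly one predicted class.

    By default occurrence is by gene, not by condition: a gene used with
    both <= and > within one class still counts once for that class, and any
    appearance on a rule's path counts. Classes without any exclusive gene
    are absent from the report.

    Note that for a tree grown to purity on distinct cells every internal
    node has leaves of at least two classes beneath it, so under the default
    counting every path gene occurs in several classes' rules and the report
    is empty; exclusivity only arises when leaves may be impure (duplicated
    cells or min_samples_leaf > 1) or under the relaxed counting below.

    Parameters
    ----------
    min_support
        Ignore rules supported by fewer training cells (rule triage).
    positive_only
        Count a gene only where it appears with the ">" (elevated) relation,
        i.e. where high expression argues for the rule's class.
    """
    if not rules:
        raise ValueError("empty rule list")
    gene_classes: dict[str, set] = {}
    for rule in rules:
        if rule.support < min_support:
            continue
        for g, rel, _ in rule.conditions:
            if positive_only and rel != ">":
                continue
            gene_classes.setdefault(g, set()).add(rule.predicted_class)
    mapping: dict[str, set] = {}
    for g, cs in gene_classes.items():
        if len(cs) == 1:
            mapping.setdefault(next(iter(cs)), set()).add(g)
    return ExclusiveGeneReport(mapping)


def rules_to_frame(rules: list[DecisionRule]) -> pd.DataFrame:
    return pd.DataFrame({
        "rule_id": np.arange(len(rules)),
        "class": [r.predicted_class for r in rules],
        "support": [r.support for r in rules],
        "purity": [r.purity for r in rules],
        "conditions": [r.condition_string() for r in rules],
    })
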