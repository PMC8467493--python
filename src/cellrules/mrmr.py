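"""Max-Relevance Min-Redundancy gene ranking on discretized expression.

Expression is discretized per gene into three states around the gene's own
mean (below mean - sd, within, above mean + sd -> -1/0/+1), the classical
default of the reference mRMR program. Mutual information is the plug-in
(empirical contingency) estimator in bits. Ranking is greedy forward
selection under the MID (difference) criterion: the first pick maximizes
MI(gene, label); each later pick maximizes

    MI(gene, label) - (1/|S|) * sum_{s in S} MI(gene, s)

over genes not yet selected, S being the selected set. Ties break by input
gene order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from cellrules.datamodel import LabeledDataset

_LN2 = float(np.log(2.0))


@dataclass
class DiscretizedMatrix:
    """Three-state (-1/0/+1) discretization of an expression matrix."""

    states: np.ndarray          # cells x genes, int8
    thresholds: np.ndarray      # genes x 2: (mean - sd, mean + sd)
    gene_ids: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.states.shape[1]


@dataclass
class RankedGeneList:
    """Genes in decreasing mRMR importance with their selection-time scores."""

    gene_ids: list
    scores: list

    def __len__(self) -> int:
        return len(self.gene_ids)

    def top(self, n: int) -> list:
        return self.gene_ids[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.gene_ids) + 1),
            "gene_id": self.gene_ids,
            "score": self.scores,
        })

    def save(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def discretize(ds: LabeledDataset) -> DiscretizedMatrix:
    """Per-gene mean +/- sd three-state discretization.

    A constant gene (sd = 0) maps to all zeros.
    """
    mu = ds.matrix.mean(axis=0)
    sd = ds.matrix.std(axis=0)
    lo, hi = mu - sd, mu + sd
    states = np.zeros(ds.matrix.shape, dtype=np.int8)
    states[ds.matrix < lo] = -1
    states[ds.matrix > hi] = 1
    return DiscretizedMatrix(states, np.column_stack([lo, hi]), ds.gene_ids)


def mutual_information(x, y) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    MI(x, x) equals the empirical entropy of x.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if x.size == 0:
        raise ValueError("empty vectors")
    return float(mutual_info_score(x, y)) / _LN2


def _mi_bits_from_counts(counts: np.ndarray) -> np.ndarray:
    """Plug-in MI in bits from a batch of contingency tables (g x r x c)."""
    n = counts.sum(axis=(1, 2), keepdims=True)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return np.nan_to_num(terms, nan=0.0, posinf=0.0, neginf=0.0).sum(axis=(1, 2))


def rank_mrmr(dm: DiscretizedMatrix, labels) -> RankedGeneList:
    """Greedy MID forward selection producing a total order over all genes."""
    labels = np.asarray(labels)
    n = dm.n_genes
    if n < 1:
        raise ValueError("need at least 1 gene")
    if len(labels) != dm.states.shape[0]:
        raise ValueError("label length mismatch")

    n_cells = dm.states.shape[0]
    # one-hot encode the 3 states per gene for batched contingency products
    onehot = np.stack(
        [(dm.states == s).astype(float) for s in (-1, 0, 1)], axis=2
    )  # cells x genes x 3
    _, y_codes = np.unique(labels.astype(str), return_inverse=True)
    y_onehot = np.eye(int(y_codes.max()) + 1)[y_codes]  # cells x K

    # relevance: contingency of each gene against the label in one product
    cy = np.einsum("ngs,nk->gsk", onehot, y_onehot)
    relevance = _mi_bits_from_counts(cy)

    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(n)        # sum of MI(candidate, s) over selected s
    remaining = np.ones(n, dtype=bool)

    for _ in range(n):
        k = len(selected)
        crit = relevance - (red_sum / k if k else 0.0)
        crit = np.where(remaining, crit, -np.inf)
        # input-order tie-break, robust to float noise in the MI sums
        pick = int(np.flatnonzero(crit >= crit.max() - 1e-12)[0])
        selected.append(pick)
        scores.append(float(crit[pick]))
        remaining[pick] = False
        if remaining.any():
            # contingency of the picked gene against every other gene
            cp = np.einsum("ngs,nt->gst", onehot, onehot[:, pick, :])
            red_sum += _mi_bits_from_counts(cp)

    return RankedGeneList([dm.gene_ids[i] for i in selected], scores)
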