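"""Synthetic minority oversampling (SMOTE) by within-class interpolation.

Every class below the majority size is filled up to it by repeatedly picking
a random member a, one of its k nearest same-class neighbors b (Euclidean
distance, ties broken by cell index order), and emitting

    c = a + r * (b - a),   r ~ Uniform(0, 1),

a convex combination, so synthetic values stay within the parents' bounding
box and remain non-negative. Inside cross-validation this should be applied
to training folds only (the metrics module's default) to avoid leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from cellrules.datamodel import LabeledDataset, class_sizes


@dataclass
class BalancedDataset:
    """A LabeledDataset whose classes all have the majority count, plus
    provenance: a per-cell synthetic flag and, for each synthetic cell, the
    row indices of its two parents (into the balanced matrix) and the
    interpolation weight r."""

    dataset: LabeledDataset
    synthetic: np.ndarray       # bool mask, aligned with dataset rows
    parents: np.ndarray         # n_synthetic x 2 int, rows in dataset.matrix
    weights: np.ndarray         # n_synthetic floats in [0, 1]

    @property
    def n_original(self) -> int:
        return int((~self.synthetic).sum())


def smote_balance(ds: LabeledDataset, k: int = 5, seed: int = 0) -> BalancedDataset:
    """Oversample every minority class up to the majority-class size."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sizes = class_sizes(ds).entries
    target = max(sizes.values())
    labels = ds.labels.astype(str)
    rng = np.random.default_rng(seed)

    new_rows, new_labels, new_ids = [], [], []
    parent_rows, weights = [], []
    for c in sorted(sizes):
        need = target - sizes[c]
        if need == 0:
            continue
        if sizes[c] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 cells; no neighbor exists")
        member_idx = np.flatnonzero(labels == c)
        members = ds.matrix[member_idx]
        kk = min(k, len(members) - 1)
        dist = cdist(members, members)
        np.fill_diagonal(dist, np.inf)
        # stable argsort -> distance ties resolved by cell index order
        neighbors = np.argsort(dist, axis=1, kind="stable")[:, :kk]
        for i in range(need):
            a = int(rng.integers(len(members)))
            b = int(neighbors[a, rng.integers(kk)])
            r = rng.random()
            new_rows.append(members[a] + r * (members[b] - members[a]))
            new_labels.append(c)
            new_ids.append(f"synth_{c}_{i:05d}")
            parent_rows.append((member_idx[a], member_idx[b]))
            weights.append(r)

    if not new_rows:
        return BalancedDataset(ds, np.zeros(ds.n_cells, dtype=bool),
                               np.empty((0, 2), dtype=int), np.empty(0))

    mat = np.vstack([ds.matrix, np.asarray(new_rows)])
    out = LabeledDataset(
        mat,
        ds.gene_ids,
        np.concatenate([ds.cell_ids, np.array(new_ids, dtype=object)]),
        np.concatenate([ds.labels, np.array(new_labels, dtype=object)]),
    )
    flag = np.zeros(out.n_cells, dtype=bool)
    flag[ds.n_cells:] = True
    return BalancedDataset(out, flag, np.asarray(parent_rows, dtype=int),
                           np.asarray(weights))
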