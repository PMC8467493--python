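"""Labeled expression dataset: container, I/O, and the class-size filter.

The universal currency of the pipeline is a cells x genes matrix of
non-negative normalized expression values (log2(TPM+1) scale) with one
class tag per cell (e.g. a tissue x cell-type label).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class DatasetError(ValueError):
    """Raised when a dataset violates its invariants or cannot be read."""


@dataclass
class LabeledDataset:
    """Cells x genes expression matrix with per-cell class labels.

    Invariants (checked at construction): values finite and >= 0,
    unique cell and gene ids, one label per matrix row.
    """

    matrix: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.matrix.ndim != 2:
            raise DatasetError("matrix must be 2-dimensional (cells x genes)")
        n_cells, n_genes = self.matrix.shape
        if len(self.cell_ids) != n_cells:
            raise DatasetError("cell_ids length does not match matrix rows")
        if len(self.gene_ids) != n_genes:
            raise DatasetError("gene_ids length does not match matrix columns")
        if len(self.labels) != n_cells:
            raise DatasetError("labels length does not match number of cells")
        if not np.all(np.isfinite(self.matrix)):
            raise DatasetError("matrix contains NaN or infinite values")
        if np.any(self.matrix < 0):
            raise DatasetError("matrix contains negative values")
        if len(set(self.cell_ids)) != n_cells:
            raise DatasetError("duplicate cell ids")
        if len(set(self.gene_ids)) != n_genes:
            raise DatasetError("duplicate gene ids")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def classes(self) -> list:
        """Sorted list of distinct class tags present."""
        return sorted(set(self.labels))

    def gene_index(self, genes) -> np.ndarray:
        """Column indices of the given gene ids (order preserved)."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([pos[g] for g in genes], dtype=int)
        except KeyError as e:
            raise DatasetError(f"unknown gene id: {e.args[0]!r}") from None

    def subset_genes(self, genes) -> "LabeledDataset":
        idx = self.gene_index(genes)
        return LabeledDataset(
            self.matrix[:, idx], np.asarray(list(genes), dtype=object),
            self.cell_ids, self.labels,
        )

    def subset_cells(self, mask_or_idx) -> "LabeledDataset":
        return LabeledDataset(
            self.matrix[mask_or_idx], self.gene_ids,
            self.cell_ids[mask_or_idx], self.labels[mask_or_idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class ClassSizeTable:
    """Per-class cell counts; sums to the dataset's cell count."""

    entries: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(sum(self.entries.values()))

    def __getitem__(self, key):
        return self.entries[key]

    def __len__(self):
        return len(self.entries)


def _read_labels(labels_path: str) -> pd.Series:
    df = pd.read_csv(labels_path, sep=None, engine="python", header=None,
                     dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DatasetError("labels file must have two columns: cell_id, class_tag")
    # tolerate a header row
    first = df.iloc[0, 0].lower()
    if first in ("cell_id", "cell", "barcode", "id"):
        df = df.iloc[1:]
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if s.index.duplicated().any():
        dup = s.index[s.index.duplicated()][0]
        raise DatasetError(f"duplicate cell id in labels file: {dup!r}")
    return s


def _sidecar(path: str, suffix: str) -> str:
    stem, _ = os.path.splitext(path)
    return stem + suffix


def load_dataset(matrix_path: str, labels_path: str, format: str = "dense",
                 genes_path: str | None = None,
                 cells_path: str | None = None) -> LabeledDataset:
    """Read an expression matrix plus labels file into a LabeledDataset.

    Parameters
    ----------
    matrix_path
        Dense delimited matrix (header row of gene ids, first column of cell
        ids; comma or tab, sniffed; .gz accepted) or a matrix-market ``.mtx``
        triplet file (cells x genes).
    labels_path
        Two-column delimited file mapping every cell id to one class tag.
    format
        ``"dense"`` or ``"mtx"``. For ``"mtx"``, gene and cell ids come from
        sidecar text files (one id per line) — by default ``<stem>.genes.txt``
        and ``<stem>.cells.txt`` next to the matrix.
    """
    for p in (matrix_path, labels_path):
        if not os.path.exists(p):
            raise DatasetError(f"file not found: {p}")
    if format == "dense":
        df = pd.read_csv(matrix_path, sep=None, engine="python", index_col=0)
        mat = df.to_numpy(dtype=float)
        gene_ids = df.columns.to_numpy(dtype=object)
        cell_ids = df.index.to_numpy(dtype=object).astype(str).astype(object)
    elif format == "mtx":
        genes_path = genes_path or _sidecar(matrix_path, ".genes.txt")
        cells_path = cells_path or _sidecar(matrix_path, ".cells.txt")
        for p in (genes_path, cells_path):
            if not os.path.exists(p):
                raise DatasetError(f"sidecar file not found: {p}")
        mat = np.asarray(mmread(matrix_path).todense(), dtype=float)
        gene_ids = np.loadtxt(genes_path, dtype=str, ndmin=1).astype(object)
        cell_ids = np.loadtxt(cells_path, dtype=str, ndmin=1).astype(object)
    else:
        raise DatasetError(f"unknown format: {format!r}")

    label_map = _read_labels(labels_path)
    missing = [c for c in cell_ids if c not in label_map.index]
    if missing:
        raise DatasetError(f"unlabeled cell: {missing[0]!r}")
    extra = set(label_map.index) - set(cell_ids)
    if extra:
        raise DatasetError(f"label for unknown cell: {sorted(extra)[0]!r}")
    labels = label_map.loc[list(cell_ids)].to_numpy(dtype=object)
    return LabeledDataset(mat, gene_ids, cell_ids, labels)


def save_dataset(ds: LabeledDataset, matrix_path: str, labels_path: str,
                 format: str = "dense") -> None:
    """Write a dataset in the dense delimited dialect or matrix-market triplet.

    The dense dialect round-trips matrix values bit-identically (full repr
    precision).
    """
    if format == "dense":
        sep = "," if matrix_path.endswith(".csv") else "\t"
        df = ds.to_frame()
        df.to_csv(matrix_path, sep=sep, float_format=None)
    elif format == "mtx":
        mmwrite(matrix_path, coo_matrix(ds.matrix))
        np.savetxt(_sidecar(matrix_path, ".genes.txt"), ds.gene_ids, fmt="%s")
        np.savetxt(_sidecar(matrix_path, ".cells.txt"), ds.cell_ids, fmt="%s")
    else:
        raise DatasetError(f"unknown format: {format!r}")
    pd.DataFrame({"cell_id": ds.cell_ids, "class": ds.labels}).to_csv(
        labels_path, sep="\t", header=False, index=False)


def class_sizes(ds: LabeledDataset) -> ClassSizeTable:
    """Count cells per class tag."""
    vals, counts = np.unique(ds.labels.astype(str), return_counts=True)
    return ClassSizeTable(dict(zip(vals.tolist(), counts.astype(int).tolist())))


def filter_cell_types(ds: LabeledDataset, min_cells: int = 100) -> LabeledDataset:
    """Keep only cells whose class has strictly more than ``min_cells`` members.

    Classes with exactly ``min_cells`` cells are dropped (strict inequality).
    """
    sizes = class_sizes(ds)
    keep = {c for c, n in sizes.entries.items() if n > min_cells}
    if not keep:
        raise DatasetError("no class passes filter")
    mask = np.array([str(l) in keep for l in ds.labels], dtype=bool)
    return ds.subset_cells(mask)
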