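"""Synthetic labeled expression matrices with planted marker structure.

Emulates the statistical features of a normalized (log2(TPM+1)) single-cell
matrix that the pipeline's feature-selection stages assume: many
uninformative genes identically distributed across classes, a minority of
class-discriminative genes with an additive mean shift, some genes private
to a single class, strongly imbalanced class sizes, dropout zeros, and
non-negative continuous values. Gene names encode the planted truth
("noise_0007", "mk_A_01", "pv_B_03") so recovery can be asserted without
carrying the GroundTruth object through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cellrules.datamodel import LabeledDataset

_CLASS_NAMES = [chr(ord("A") + i) for i in range(26)]


@dataclass
class SyntheticConfig:
    """Generative parameters for a planted-marker expression dataset.

    Defaults mirror the benchmark condition used throughout the test
    battery: 3 classes of imbalanced sizes [200, 50, 50], 100 noise genes,
    5 private markers per class, a +2 log-unit effect, noise sd 0.5.
    """

    n_classes: int = 3
    class_sizes: tuple = (200, 50, 50)
    n_noise_genes: int = 100
    shared_markers_per_class: int = 0
    private_markers_per_class: int = 5
    effect_size: float = 2.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.1
    baseline_mean: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if len(self.class_sizes) != self.n_classes:
            raise ValueError("class_sizes length must equal n_classes")
        if any(s <= 0 for s in self.class_sizes):
            raise ValueError("class sizes must be positive")
        if self.n_noise_genes < 0:
            raise ValueError("n_noise_genes must be >= 0")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.effect_size < 0 or self.noise_sd <= 0:
            raise ValueError("effect_size must be >= 0 and noise_sd > 0")

    @property
    def class_names(self) -> list[str]:
        if self.n_classes <= 26:
            return _CLASS_NAMES[: self.n_classes]
        return [f"C{i:03d}" for i in range(self.n_classes)]

    @property
    def n_genes(self) -> int:
        per_class = self.shared_markers_per_class + self.private_markers_per_class
        return self.n_noise_genes + self.n_classes * per_class


@dataclass
class GroundTruth:
    """Which genes were planted as markers, and which are private.

    ``private_map[c]`` is a subset of ``marker_map[c]``; private markers of
    distinct classes are disjoint.
    """

    marker_map: dict = field(default_factory=dict)
    private_map: dict = field(default_factory=dict)

    @property
    def all_markers(self) -> set:
        out: set = set()
        for s in self.marker_map.values():
            out |= s
        return out


def generate(cfg: SyntheticConfig) -> tuple[LabeledDataset, GroundTruth]:
    """Draw a labeled dataset with planted markers.

    Baseline expression is Normal(baseline_mean, noise_sd) rectified at zero
    on the log scale, identical across classes. Each marker gene receives a
    +effect_size mean shift in its owning class; a shared marker is shifted
    in its owning class and in the cyclically next class, so it
    discriminates without being class-exclusive. Dropout then zeroes each
    entry independently with probability dropout_rate. Identical config
    (including seed) gives bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = cfg.class_names
    n_cells = int(sum(cfg.class_sizes))

    labels = np.concatenate(
        [np.repeat(names[i], s) for i, s in enumerate(cfg.class_sizes)]
    ).astype(object)
    cell_ids = np.array([f"cell_{i:05d}" for i in range(n_cells)], dtype=object)

    gene_ids: list[str] = [f"noise_{i:04d}" for i in range(cfg.n_noise_genes)]
    shift = np.zeros((cfg.n_classes, cfg.n_genes))  # per-class additive shift
    truth = GroundTruth({c: set() for c in names}, {c: set() for c in names})

    col = cfg.n_noise_genes
    for ci, c in enumerate(names):
        for j in range(cfg.shared_markers_per_class):
            g = f"mk_{c}_{j:02d}"
            gene_ids.append(g)
            shift[ci, col] = cfg.effect_size
            shift[(ci + 1) % cfg.n_classes, col] = cfg.effect_size
            truth.marker_map[c].add(g)
            col += 1
        for j in range(cfg.private_markers_per_class):
            g = f"pv_{c}_{j:02d}"
            gene_ids.append(g)
            shift[ci, col] = cfg.effect_size
            truth.marker_map[c].add(g)
            truth.private_map[c].add(g)
            col += 1

    class_idx = np.concatenate(
        [np.repeat(i, s) for i, s in enumerate(cfg.class_sizes)]
    )
    base = rng.normal(cfg.baseline_mean, cfg.noise_sd, size=(n_cells, cfg.n_genes))
    mat = np.maximum(base + shift[class_idx], 0.0)
    if cfg.dropout_rate > 0:
        mat[rng.random(mat.shape) < cfg.dropout_rate] = 0.0

    ds = LabeledDataset(mat, np.array(gene_ids, dtype=object), cell_ids, labels)
    return ds, truth
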