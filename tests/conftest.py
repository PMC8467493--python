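import numpy as np
import pytest

from cellrules import LabeledDataset, SyntheticConfig, generate


@pytest.fixture
def tiny_ds():
    """3 cells x 2 genes, two classes, hand-written values."""
    return LabeledDataset(
        matrix=np.array([[1.0, 0.0], [2.0, 0.5], [0.0, 3.0]]),
        gene_ids=np.array(["g1", "g2"], dtype=object),
        cell_ids=np.array(["c1", "c2", "c3"], dtype=object),
        labels=np.array(["A", "A", "B"], dtype=object),
    )


@pytest.fixture(scope="session")
def bench_ds():
    """The benchmark synthetic condition: 3 classes, sizes (200, 50, 50),
    100 noise genes, 5 private markers per class, effect +2, sd 0.5."""
    ds, truth = generate(SyntheticConfig(seed=7))
    return ds, truth


@pytest.fixture(scope="session")
def small_ds():
    """A faster synthetic dataset for unit tests of the heavier stages."""
    cfg = SyntheticConfig(
        n_classes=3, class_sizes=(60, 30, 30), n_noise_genes=20,
        private_markers_per_class=3, effect_size=2.0, noise_sd=0.5,
        dropout_rate=0.1, seed=11,
    )
    ds, truth = generate(cfg)
    return ds, truth
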