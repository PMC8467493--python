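import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cellrules import (DiscretizedMatrix, LabeledDataset, discretize,
                       mutual_information, rank_mrmr)


def mi_oracle(x, y):
    """Plug-in MI in bits from explicit cell counting (independent of the
    package's estimator path)."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        p = c / n
        total += p * math.log2(p / ((px[a] / n) * (py[b] / n)))
    return total


def greedy_mid_oracle(X, y):
    """Exhaustive step-wise recomputation of the MID criterion."""
    cols = list(range(X.shape[1]))
    selected = []
    while cols:
        best, best_v = None, -np.inf
        for j in cols:
            rel = mi_oracle(X[:, j].tolist(), list(y))
            red = (np.mean([mi_oracle(X[:, j].tolist(), X[:, s].tolist())
                            for s in selected]) if selected else 0.0)
            v = rel - red
            if v > best_v + 1e-12:
                best, best_v = j, v
        selected.append(best)
        cols.remove(best)
    return selected


def make_dm(X):
    return DiscretizedMatrix(
        X.astype(np.int8), np.zeros((X.shape[1], 2)),
        np.array([f"g{j}" for j in range(X.shape[1])], dtype=object),
    )


class TestDiscretize:
    def test_constant_gene_all_zero(self, tiny_ds):
        ds = LabeledDataset(np.full((4, 1), 2.5), ["g"],
                            [f"c{i}" for i in range(4)], ["A", "A", "B", "B"])
        assert np.all(discretize(ds).states == 0)

    def test_single_outlier_gets_plus_one(self):
        vals = np.array([0.0] * 9 + [10.0])
        ds = LabeledDataset(vals[:, None], ["g"],
                            [f"c{i}" for i in range(10)], ["A"] * 5 + ["B"] * 5)
        states = discretize(ds).states[:, 0]
        mu, sd = vals.mean(), vals.std()
        assert vals[9] > mu + sd           # sanity of the hand computation
        assert states[9] == 1
        assert np.all(states[:9] == 0) or np.all(states[:9] == -1)

    def test_invariant_to_cell_order(self, small_ds):
        ds, _ = small_ds
        perm = np.random.default_rng(0).permutation(ds.n_cells)
        shuffled = ds.subset_cells(perm)
        assert np.array_equal(discretize(shuffled).states,
                              discretize(ds).states[perm])


class TestMutualInformation:
    def test_constant_is_zero(self):
        assert mutual_information([1] * 8, [0, 1] * 4) == pytest.approx(0.0)

    def test_identical_binary_half_half_is_one_bit(self):
        x = [0, 1] * 10
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_known_joint_counts(self):
        # joint [[2,1],[1,2]], n = 6
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2], [1])

    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 3)),
                    min_size=1, max_size=60))
    @settings(deadline=None, derandomize=True)
    def test_symmetry_and_entropy_bound(self, pairs):
        x = [a for a, _ in pairs]
        y = [b for _, b in pairs]
        mxy = mutual_information(x, y)
        assert mxy == pytest.approx(mutual_information(y, x), abs=1e-12)
        hx = mutual_information(x, x)
        hy = mutual_information(y, y)
        assert mxy <= min(hx, hy) + 1e-12
        assert mxy >= -1e-12


class TestRankMrmr:
    def test_single_gene(self):
        X = np.array([[-1], [0], [1], [1]])
        y = ["A", "A", "B", "B"]
        out = rank_mrmr(make_dm(X), y)
        assert out.gene_ids == ["g0"]
        assert out.scores[0] == pytest.approx(
            mi_oracle(X[:, 0].tolist(), y), abs=1e-12)

    def test_duplicate_gene_penalized(self):
        """f1 informative, f2 an exact copy of f1, f3 independent: after f1,
        the redundancy penalty puts f3 second."""
        rng = np.random.default_rng(3)
        y = np.array(["A"] * 30 + ["B"] * 30)
        f1 = np.where(y == "A", -1, 1)
        flip = rng.random(60) < 0.15
        f1 = np.where(flip, -f1, f1)
        f3 = rng.integers(-1, 2, 60)
        X = np.column_stack([f1, f1, f3])
        out = rank_mrmr(make_dm(X), y)
        assert out.gene_ids[0] == "g0"      # tie with g1 broken by input order
        assert out.gene_ids[1] == "g2"

    def test_output_is_permutation(self, small_ds):
        ds, _ = small_ds
        out = rank_mrmr(discretize(ds), ds.labels)
        assert sorted(out.gene_ids) == sorted(ds.gene_ids)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(2, 7))
        X = rng.integers(-1, 2, size=(40, n_genes))
        y = rng.integers(0, 3, size=40).astype(str)
        got = [int(g[1:]) for g in rank_mrmr(make_dm(X), y).gene_ids]
        assert got == greedy_mid_oracle(X, y)

    def test_markers_outrank_noise(self, small_ds):
        ds, truth = small_ds
        order = rank_mrmr(discretize(ds), ds.labels).gene_ids
        ranks = {g: i for i, g in enumerate(order)}
        noise_ranks = [ranks[g] for g in ds.gene_ids if str(g).startswith("noise")]
        median_noise = np.median(noise_ranks)
        assert all(ranks[g] < median_noise for g in truth.all_markers)
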