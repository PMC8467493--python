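import numpy as np
import pytest

from cellrules import (LabeledDataset, SyntheticConfig, exclusive_genes,
                       extract_rules, generate, train_rule_tree)
from cellrules.rules import DecisionRule, rules_to_frame


def two_class_one_gene_ds():
    """Two classes cleanly separated by g1 around 5."""
    vals = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 9.0])
    return LabeledDataset(
        np.column_stack([vals, np.zeros(6)]), ["g1", "g2"],
        [f"c{i}" for i in range(6)],
        ["A"] * 3 + ["B"] * 3,
    )


class TestTrainAndExtract:
    def test_single_split_near_boundary(self):
        ds = two_class_one_gene_ds()
        tree = train_rule_tree(ds, ["g1", "g2"], seed=0)
        rules = extract_rules(tree)
        assert len(rules) == 2
        (r1, r2) = rules
        assert len(r1.conditions) == len(r2.conditions) == 1
        g1, rel1, thr1 = r1.conditions[0]
        g2, rel2, thr2 = r2.conditions[0]
        assert g1 == g2 == "g1" and thr1 == thr2
        assert {rel1, rel2} == {"<=", ">"}
        assert 3.0 < thr1 < 7.0
        assert {r1.predicted_class, r2.predicted_class} == {"A", "B"}

    def test_pure_data_single_leaf(self):
        ds = LabeledDataset(np.arange(8, dtype=float).reshape(4, 2),
                            ["g1", "g2"], [f"c{i}" for i in range(4)],
                            ["A"] * 4)
        rules = extract_rules(train_rule_tree(ds, ["g1", "g2"], seed=0))
        assert len(rules) == 1
        assert rules[0].conditions == []
        assert rules[0].support == 4 and rules[0].purity == 1.0

    def test_seeded_rerun_identical(self, small_ds):
        ds, _ = small_ds
        genes = list(ds.gene_ids)
        r1 = extract_rules(train_rule_tree(ds, genes, seed=5))
        r2 = extract_rules(train_rule_tree(ds, genes, seed=5))
        assert rules_to_frame(r1).equals(rules_to_frame(r2))

    def test_empty_gene_subset_rejected(self, small_ds):
        ds, _ = small_ds
        with pytest.raises(ValueError, match="empty gene subset"):
            train_rule_tree(ds, [], seed=0)

    def test_unfitted_tree_rejected(self):
        from sklearn.tree import DecisionTreeClassifier

        with pytest.raises(ValueError, match="not fitted"):
            extract_rules(DecisionTreeClassifier())


@pytest.mark.parametrize("seed", range(3))
def test_rules_partition_training_cells(seed):
    """One rule per leaf; every training cell satisfies exactly one rule's
    conjunction; supports sum to N."""
    cfg = SyntheticConfig(
        n_classes=3, class_sizes=(40, 25, 15), n_noise_genes=10,
        private_markers_per_class=2, dropout_rate=0.2, seed=seed,
    )
    ds, _ = generate(cfg)
    genes = list(ds.gene_ids)
    tree = train_rule_tree(ds, genes, seed=seed)
    rules = extract_rules(tree)
    assert len(rules) == tree.tree_.n_leaves
    assert sum(r.support for r in rules) == ds.n_cells
    gene_pos = {g: i for i, g in enumerate(genes)}
    for row in ds.matrix:
        assert sum(r.matches(row, gene_pos) for r in rules) == 1


class TestExclusiveGenes:
    def test_hand_rules(self):
        rules = [
            DecisionRule([("g1", "<=", 2.0)], "A", 5, 1.0),
            DecisionRule([("g2", ">", 1.0)], "B", 5, 1.0),
        ]
        assert exclusive_genes(rules).mapping == {"A": {"g1"}, "B": {"g2"}}

    def test_cross_class_gene_excluded_everywhere(self):
        rules = [
            DecisionRule([("g1", ">", 1.0)], "A", 5, 1.0),
            DecisionRule([("g1", "<=", 1.0), ("g2", ">", 0.5)], "B", 5, 1.0),
        ]
        report = exclusive_genes(rules).mapping
        assert "g1" not in report.get("A", set())
        assert report == {"B": {"g2"}}

    def test_both_relations_within_one_class_still_count(self):
        rules = [
            DecisionRule([("g1", "<=", 3.0), ("g1", ">", 1.0)], "A", 5, 1.0),
        ]
        assert exclusive_genes(rules).mapping == {"A": {"g1"}}

    def test_relabeling_symmetry(self):
        rules = [
            DecisionRule([("g1", ">", 1.0)], "A", 5, 1.0),
            DecisionRule([("g2", ">", 1.0)], "B", 5, 1.0),
        ]
        swapped = [
            DecisionRule(r.conditions, {"A": "B", "B": "A"}[r.predicted_class],
                         r.support, r.purity)
            for r in rules
        ]
        direct = exclusive_genes(rules).mapping
        relabeled = exclusive_genes(swapped).mapping
        assert relabeled == {"B": direct["A"], "A": direct["B"]}

    def test_purity_tree_genes_are_never_exclusive(self, small_ds):
        """Structural fact: in a tree grown to purity on distinct cells,
        every internal node has leaves of >= 2 classes beneath it, so each
        path gene occurs in several classes' rules and the by-gene
        exclusivity report is empty."""
        ds, _ = small_ds
        rules = extract_rules(train_rule_tree(ds, list(ds.gene_ids), seed=0))
        assert exclusive_genes(rules).mapping == {}

    def test_positive_only_counting_recovers_markers(self, small_ds):
        """Counting only elevated (>) occurrences attributes private markers
        to their own class."""
        ds, truth = small_ds
        rules = extract_rules(train_rule_tree(ds, sorted(truth.all_markers),
                                              seed=0))
        report = exclusive_genes(rules, positive_only=True).mapping
        for c, genes in report.items():
            for g in genes:
                if g.startswith("pv_"):
                    assert g in truth.private_map[c]

    def test_report_genes_subset_of_tree_genes(self, small_ds):
        ds, _ = small_ds
        genes = list(ds.gene_ids)[:10]
        tree = train_rule_tree(ds, genes, seed=1)
        report = exclusive_genes(extract_rules(tree), positive_only=True)
        used = set().union(*(set(v) for v in report.mapping.values())) \
            if report.mapping else set()
        assert used <= set(genes)

    def test_empty_rule_list_rejected(self):
        with pytest.raises(ValueError):
            exclusive_genes([])
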