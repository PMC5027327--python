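import math

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from neurotree.preprocess import FeatureTable
from neurotree.tree import (
    TreeParams,
    best_split,
    entropy,
    extract_rules,
    gain_ratio,
    induce_tree,
    model_from_json,
    model_to_json,
    predict,
    predict_table,
    render_dot,
    render_indented,
    resubstitution_accuracy,
)

from conftest import make_table


def table_from(values, labels, name="x"):
    frame = pd.DataFrame({"Time": range(1, len(values) + 1), name: values,
                          "Class": labels})
    return FeatureTable(frame)


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected",
        [([8, 8], 1.0), ([16, 0], 0.0), ([4, 4, 4, 4], 2.0), ([1], 0.0)],
    )
    def test_known_values(self, counts, expected):
        assert entropy(counts) == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            entropy([0, 0])


class TestGainRatio:
    def test_perfect_binary_separation(self):
        assert gain_ratio([5, 5], [5, 0], [0, 5]) == pytest.approx(1.0)

    def test_degenerate_one_sided_split_is_zero(self):
        assert gain_ratio([5, 5], [5, 5], [0, 0]) == 0.0

    def test_hand_computed_six_instance_case(self):
        # parent [3,3] split into [2,1] and [1,2]; oracle arithmetic inline
        h = lambda p: 0.0 if p in (0, 1) else -p * math.log2(p) - (1 - p) * math.log2(1 - p)
        gain = h(0.5) - 0.5 * h(2 / 3) - 0.5 * h(1 / 3)
        split_info = h(0.5)
        assert gain_ratio([3, 3], [2, 1], [1, 2]) == pytest.approx(gain / split_info)

    def test_inconsistent_partition_rejected(self):
        with pytest.raises(ValueError):
            gain_ratio([3, 3], [2, 1], [2, 2])


class TestBestSplit:
    def test_midpoint_of_perfect_split(self):
        table = table_from([0.0, 0.0, 1.0, 1.0], ["a", "a", "b", "b"])
        thr, ratio = best_split(table, "x")
        assert thr == pytest.approx(0.5)
        assert ratio == pytest.approx(1.0)

    def test_constant_attribute_has_no_split(self):
        table = table_from([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert best_split(table, "x") is None

    def test_min_leaf_count_filters_candidates(self):
        table = table_from([0.0, 1.0, 2.0, 3.0], ["a", "b", "a", "b"])
        # only the 1|3 and 3|1 splits are informative; the centred 2|2 split
        # has zero gain, so min leaf 2 leaves no admissible candidate
        assert best_split(table, "x", min_leaf_count=1) is not None
        assert best_split(table, "x", min_leaf_count=2) is None


class TestInduceAndPredict:
    def test_linearly_separable_toy_gives_depth_one_tree(self):
        table = table_from([0.1, 0.2, 0.8, 0.9], ["a", "a", "b", "b"])
        model = induce_tree(table, TreeParams(0.01), attributes=["x"])
        assert not model.root.is_leaf
        assert model.root.left.is_leaf and model.root.right.is_leaf
        assert resubstitution_accuracy(model, table) == 1.0

    def test_pure_table_gives_single_leaf(self):
        table = table_from([1.0, 2.0, 3.0], ["a", "a", "a"])
        model = induce_tree(table)
        assert model.root.is_leaf
        assert predict(model, {"anything": 0}) == "a"

    def test_empty_table_rejected(self):
        table = make_table({"a": 3, "b": 3})
        empty = FeatureTable(table.frame.iloc[0:0])
        with pytest.raises(ValueError, match="empty"):
            induce_tree(empty)

    def test_grouped_synthetic_table_classified_perfectly(self, sighted_grouped):
        model = induce_tree(sighted_grouped, TreeParams(min_leaf_fraction=0.01))
        assert resubstitution_accuracy(model, sighted_grouped) == 1.0

    @pytest.mark.parametrize(
        "instance,expected",
        [
            ({"Time": 10}, "cube"),
            ({"Time": 20, "CP1": 0.05}, "interval"),
            ({"Time": 20, "CP1": 0.2}, "ball"),
            ({"Time": 40}, "parallelogram"),
        ],
    )
    def test_prediction_follows_the_example_tree(self, example_tree, instance, expected):
        assert predict(example_tree, instance) == expected

    def test_missing_tested_attribute_named(self, example_tree):
        with pytest.raises(ValueError, match="CP1"):
            predict(example_tree, {"Time": 20})

    def test_resubstitution_perfect_without_conflicts(self):
        # unpruned, min leaf 1: any conflict-free table is fit exactly
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(4, 30))
            table = make_table(
                {"a": n, "b": n, "c": n // 2 + 1}, n_channels=2, seed=seed
            )
            model = induce_tree(
                table, TreeParams(min_leaf_fraction=1e-6 + 1 / (10 * n),
                                  pruning_enabled=False)
            )
            assert resubstitution_accuracy(model, table) == 1.0

    def test_sklearn_agrees_on_separable_data(self, sighted_grouped):
        # independent learner as cross-check: an entropy-criterion CART also
        # fits the grouped synthetic table perfectly
        X = sighted_grouped.attributes()
        y = sighted_grouped.labels
        sk = DecisionTreeClassifier(criterion="entropy", random_state=0).fit(X, y)
        assert sk.score(X, y) == 1.0
        ours = induce_tree(sighted_grouped, TreeParams(0.01))
        assert resubstitution_accuracy(ours, sighted_grouped) == 1.0


class TestPruning:
    def _noisy_table(self, seed, n=60):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, n)
        labels = np.where(
            x > 0.5, rng.choice(["a", "b"], n, p=[0.8, 0.2]),
            rng.choice(["a", "b"], n, p=[0.25, 0.75]),
        )
        return table_from(x.tolist(), labels.tolist())

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_pruning_never_grows_the_tree_nor_training_accuracy(self, seed):
        table = self._noisy_table(seed)
        params = dict(min_leaf_fraction=0.02, confidence_factor=0.25)
        full = induce_tree(table, TreeParams(pruning_enabled=False, **params))
        pruned = induce_tree(table, TreeParams(pruning_enabled=True, **params))
        assert len(pruned.leaves()) <= len(full.leaves())
        assert (
            resubstitution_accuracy(pruned, table)
            <= resubstitution_accuracy(full, table) + 1e-12
        )

    def test_min_leaf_sweep_never_increases_leaf_count(self, sighted_grouped):
        leaf_counts = [
            len(induce_tree(sighted_grouped, TreeParams(f)).leaves())
            for f in (0.01, 0.05, 0.10)
        ]
        assert leaf_counts == sorted(leaf_counts, reverse=True)

    @pytest.mark.parametrize(
        "kwargs", [dict(min_leaf_fraction=0.0), dict(min_leaf_fraction=1.0),
                   dict(confidence_factor=0.0), dict(confidence_factor=0.6)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TreeParams(**kwargs)


class TestRulesAndRendering:
    def test_example_tree_yields_four_printed_rules(self, example_tree):
        rules = extract_rules(example_tree)
        assert len(rules) == 4
        assert {r.conclusion for r in rules} == {
            "cube", "interval", "ball", "parallelogram",
        }
        thresholds = {thr for r in rules for _, _, thr in r.conditions}
        assert thresholds == {14.0, 30.0, 0.072}
        texts = [r.format() for r in rules]
        assert "Time <= 14: cube" in texts

    def test_single_leaf_tree_has_one_unconditional_rule(self):
        table = table_from([1.0, 2.0], ["a", "a"])
        model = induce_tree(table)
        rules = extract_rules(model)
        assert len(rules) == 1 and rules[0].conditions == ()

    @pytest.mark.parametrize("seed", range(20))
    def test_rule_count_equals_leaf_count(self, seed):
        rng = np.random.default_rng(seed)
        sizes = {c: int(rng.integers(3, 15)) for c in "abc"}
        table = make_table(sizes, n_channels=3, seed=seed)
        model = induce_tree(table, TreeParams(0.01, pruning_enabled=False))
        assert len(extract_rules(model)) == len(model.leaves())

    def test_rules_partition_the_training_instances(self, sighted_grouped):
        model = induce_tree(sighted_grouped, TreeParams(0.01))
        rules = extract_rules(model)
        records = sighted_grouped.frame.drop(columns=["Class"]).to_dict("records")
        for rec in records:
            matching = [
                r for r in rules
                if all(
                    (rec[a] <= t) if rel == "<=" else (rec[a] > t)
                    for a, rel, t in r.conditions
                )
            ]
            assert len(matching) == 1

    def test_indented_rendering_mentions_split_tokens(self, example_tree):
        text = render_indented(example_tree)
        assert "CP1" in text and "0.072" in text
        assert text.count("\n") + 1 == 6  # two branch lines per internal node

    def test_single_leaf_rendering_is_one_line(self):
        model = induce_tree(table_from([1.0], ["a"]))
        assert "\n" not in render_indented(model)
        assert "a" in render_indented(model)

    def test_dot_output_is_a_digraph_with_one_entry_per_node(self, example_tree):
        dot = render_dot(example_tree)
        assert dot.startswith("digraph") and dot.rstrip().endswith("}")
        assert dot.count("label=") == example_tree.node_count() + 2 * 3  # node + edge labels
        assert dot.count("shape=ellipse") == len(example_tree.leaves())

    def test_model_json_round_trip(self, sighted_grouped):
        model = induce_tree(sighted_grouped, TreeParams(0.01))
        back = model_from_json(model_to_json(model))
        assert back.classes == model.classes
        assert predict_table(back, sighted_grouped) == predict_table(
            model, sighted_grouped
        )
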