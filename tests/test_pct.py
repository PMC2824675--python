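"""Variance-reduction split induction, F-test stopping, prediction, rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pcthmc import (
    PCTParams,
    PCTree,
    apply_thresholds,
    build_tree,
    extract_rules,
    print_tree,
    variance,
    variance_reduction,
    weighted_sq_distance,
)
from pcthmc.dataset_io import Attribute, Dataset
from pcthmc.hierarchy import close_ancestors, compute_class_weights, parse_funcat_labels
from pcthmc.pct import SplitTest, enumerate_candidate_splits, f_test_acceptable
from pcthmc.synthetic import SyntheticConfig, make_dataset

from _oracles import best_split, random_dataset, two_pass_variance


def _dataset(toy_hierarchy, cols, label_rows, kinds=None):
    attrs = []
    data = {}
    for name, vals in cols.items():
        kind = (kinds or {}).get(name, "numeric")
        if kind == "nominal":
            levels = tuple(sorted({v for v in vals if v is not None}))
            attrs.append(Attribute(name, kind, levels))
            data[name] = pd.array(vals, dtype=object)
        else:
            attrs.append(Attribute(name, kind))
            data[name] = np.asarray(vals, dtype=float)
    labels = close_ancestors(toy_hierarchy, np.asarray(label_rows, np.uint8))
    return Dataset(attrs, pd.DataFrame(data), labels, toy_hierarchy)


class TestDistanceAndVariance:
    def test_toy_weighted_distance(self, toy_weights):
        d2 = weighted_sq_distance([1, 1, 0, 1, 0], [0, 1, 0, 0, 0], toy_weights)
        assert d2 == pytest.approx(0.75 + 0.5625)

    def test_distance_to_self_is_zero(self, toy_weights):
        assert weighted_sq_distance([1, 0, 1, 0, 1], [1, 0, 1, 0, 1],
                                    toy_weights) == 0.0

    def test_distance_linear_in_weights(self, toy_weights):
        v1, v2 = [1, 1, 0, 1, 0], [0, 0, 1, 0, 0]
        base = weighted_sq_distance(v1, v2, toy_weights.vector)
        doubled = weighted_sq_distance(v1, v2, 2 * toy_weights.vector)
        assert doubled == pytest.approx(2 * base)

    def test_identical_vectors_have_zero_variance(self, toy_weights):
        Y = np.tile([1, 1, 0, 0, 0], (4, 1))
        assert variance(Y, toy_weights) == 0.0

    def test_two_vector_example(self):
        # two flat top-level classes, both weight w0=0.75
        h = parse_funcat_labels(["a", "b"])
        w = compute_class_weights(h, 0.75)
        Y = np.array([[1, 0], [0, 0]])
        assert variance(Y, w) == pytest.approx(0.1875)

    @given(st.integers(0, 2**31 - 1))
    def test_variance_decomposes_over_classes(self, seed):
        rng = np.random.default_rng(seed)
        Y = (rng.random((12, 5)) < 0.4).astype(float)
        w = rng.random(5) + 0.1
        per_class = sum(wi * Y[:, i].var() for i, wi in enumerate(w))
        assert variance(Y, w) == pytest.approx(per_class, abs=1e-12)
        assert variance(Y, w) == pytest.approx(two_pass_variance(Y, w), abs=1e-12)

    def test_empty_set_rejected(self, toy_weights):
        with pytest.raises(ValueError):
            variance(np.empty((0, 5)), toy_weights)


class TestCandidateEnumeration:
    def test_numeric_midpoints(self, toy_hierarchy):
        d = _dataset(toy_hierarchy, {"x": [1.0, 2.0, 4.0]},
                     [[0] * 5] * 3)
        cands = enumerate_candidate_splits(d, range(3))
        assert [(c.kind, c.threshold) for c in cands] == [
            ("numeric_gt", 1.5), ("numeric_gt", 3.0)]

    def test_constant_attribute_yields_nothing(self, toy_hierarchy):
        d = _dataset(toy_hierarchy, {"x": [2.0, 2.0, 2.0]}, [[0] * 5] * 3)
        assert enumerate_candidate_splits(d, range(3)) == []

    def test_binary_attribute_yields_one_candidate(self, toy_hierarchy):
        d = _dataset(toy_hierarchy, {"b": [0, 1, 1]}, [[0] * 5] * 3,
                     kinds={"b": "binary"})
        cands = enumerate_candidate_splits(d, range(3))
        assert [c.kind for c in cands] == ["binary_is_one"]

    def test_nominal_one_vs_rest_per_level(self, toy_hierarchy):
        d = _dataset(toy_hierarchy, {"c": ["r", "g", "b"]}, [[0] * 5] * 3,
                     kinds={"c": "nominal"})
        cands = enumerate_candidate_splits(d, range(3))
        assert [c.subset for c in cands] == [("b",), ("g",), ("r",)]


class TestVarianceReduction:
    def test_perfect_separation_recovers_total_variance(self, toy_hierarchy,
                                                        toy_weights):
        rows = [[1, 0, 0, 0, 0]] * 3 + [[0, 0, 0, 0, 1]] * 3
        d = _dataset(toy_hierarchy, {"x": [0, 0, 0, 1, 1, 1]}, rows)
        split = SplitTest("x", "numeric_gt", threshold=0.5)
        red = variance_reduction(split, d, range(6), toy_weights, min_leaf=1)
        assert red == pytest.approx(variance(d.labels.astype(float), toy_weights))

    def test_empty_side_hits_min_leaf_sentinel(self, toy_hierarchy, toy_weights):
        d = _dataset(toy_hierarchy, {"x": [1.0, 2.0, 3.0]}, [[0] * 5] * 3)
        split = SplitTest("x", "numeric_gt", threshold=5.0)
        assert variance_reduction(split, d, range(3), toy_weights,
                                  min_leaf=1) == -np.inf

    def test_agrees_with_two_pass_oracle(self, rng, toy_weights):
        d = random_dataset(rng, n_rows=20, n_classes=5)
        w = compute_class_weights(d.hierarchy, 0.75)
        for split in enumerate_candidate_splits(d, range(20))[:10]:
            cand = (split.attribute,
                    {"numeric_gt": "numeric", "binary_is_one": "binary",
                     "nominal_in_subset": "nominal"}[split.kind],
                    split.threshold if split.kind == "numeric_gt"
                    else (split.subset[0] if split.subset else None))
            from _oracles import split_rows
            yes, no = split_rows(d, list(range(20)), cand)
            if min(len(yes), len(no)) < 2:
                continue
            Y = d.labels.astype(float)
            expected = (two_pass_variance(Y, w.vector)
                        - len(yes) / 20 * two_pass_variance(Y[yes], w.vector)
                        - len(no) / 20 * two_pass_variance(Y[no], w.vector))
            got = variance_reduction(split, d, range(20), w, min_leaf=2)
            assert got == pytest.approx(expected, abs=1e-12)


class TestFTest:
    def test_zero_reduction_not_acceptable(self):
        assert not f_test_acceptable(1.0, 1.0, 50, 0.125)

    def test_perfect_split_acceptable(self):
        assert f_test_acceptable(1.0, 0.0, 50, 0.001)

    def test_totally_pure_node_not_acceptable(self):
        assert not f_test_acceptable(0.0, 0.0, 50, 0.125)

    @given(st.integers(0, 2**31 - 1))
    def test_acceptance_monotone_in_significance(self, seed):
        rng = np.random.default_rng(seed)
        var_total = float(rng.uniform(0.1, 2.0))
        var_within = float(var_total * rng.uniform(0.3, 1.0))
        n = int(rng.integers(10, 200))
        grid = (0.001, 0.005, 0.01, 0.05, 0.1, 0.125)
        accepted = [f_test_acceptable(var_total, var_within, n, s) for s in grid]
        # once acceptable at a stringent level, acceptable at laxer ones
        assert accepted == sorted(accepted)


class TestBuildTree:
    def test_constant_labels_give_single_leaf(self, toy_hierarchy):
        d = _dataset(toy_hierarchy, {"x": list(range(10))},
                     [[1, 1, 0, 1, 0]] * 10)
        tree = build_tree(d, PCTParams())
        assert tree.root.is_leaf
        assert tree.root.prototype.tolist() == [1, 1, 0, 1, 0]

    def test_planted_single_rule_recovered_as_depth_one_tree(self):
        rng = np.random.default_rng(11)
        h = parse_funcat_labels(["2/2"])
        x = rng.random(200)
        labels = np.zeros((200, 2), np.uint8)
        labels[x > 0.5] = [1, 1]
        d = Dataset([Attribute("x", "numeric")], pd.DataFrame({"x": x}),
                    labels, h)
        tree = build_tree(d, PCTParams())
        assert not tree.root.is_leaf
        assert tree.root.test.attribute == "x"
        assert tree.root.test.threshold == pytest.approx(0.5, abs=0.02)
        assert tree.root.yes.is_leaf and tree.root.no.is_leaf

    def test_every_leaf_respects_min_leaf_default(self):
        d, _ = make_dataset(SyntheticConfig(n_classes=8, n_instances=150, seed=2,
                                            label_noise_rate=0.1))
        tree = build_tree(d, PCTParams())
        assert all(leaf.n_examples >= 5 for leaf in tree.leaves())

    def test_serialization_is_deterministic_and_round_trips(self):
        d, _ = make_dataset(SyntheticConfig(n_classes=7, n_instances=120, seed=3))
        t1 = build_tree(d, PCTParams())
        t2 = build_tree(d, PCTParams())
        assert t1.to_json() == t2.to_json()
        t3 = PCTree.from_json(t1.to_json())
        assert t3.to_json() == t1.to_json()
        np.testing.assert_array_equal(t3.predict_dataset(d),
                                      t1.predict_dataset(d))

    def test_stringent_significance_collapses_the_tree(self):
        d, _ = make_dataset(SyntheticConfig(n_classes=8, n_instances=200, seed=4,
                                            label_noise_rate=0.3))
        lax = build_tree(d, PCTParams(f_test_significance=0.125))
        strict = build_tree(d, PCTParams(f_test_significance=1e-9))
        assert strict.n_nodes() <= lax.n_nodes()

    def test_root_split_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            d = random_dataset(rng, n_rows=int(rng.integers(12, 50)),
                               n_attrs=int(rng.integers(2, 8)),
                               n_classes=int(rng.integers(2, 10)))
            w = compute_class_weights(d.hierarchy, 0.75)
            expect, _ = best_split(d, range(d.n_instances), w.vector, 2)
            tree = build_tree(d, PCTParams(min_leaf=2, f_test_significance=0.5))
            if expect is None:
                assert tree.root.is_leaf
                continue
            if tree.root.is_leaf:
                continue  # oracle found a split but the F-test rejected it
            got = tree.root.test
            name, kind, arg = expect
            assert got.attribute == name
            if kind == "numeric":
                assert got.threshold == pytest.approx(arg, abs=1e-12)
            elif kind == "nominal":
                assert got.subset == (arg,)

    def test_prototypes_are_parent_monotone(self):
        d, _ = make_dataset(SyntheticConfig(n_classes=10, n_instances=250,
                                            seed=6, label_noise_rate=0.15,
                                            dag_extra_parent_prob=0.3))
        tree = build_tree(d, PCTParams())
        for leaf in tree.leaves():
            for pi, ci in d.hierarchy.edge_index_pairs():
                assert leaf.prototype[pi] >= leaf.prototype[ci] - 1e-12


class TestPredict:
    def test_single_leaf_returns_prototype_everywhere(self, toy_hierarchy):
        d = _dataset(toy_hierarchy, {"x": [1, 2, 3, 4, 5, 6]},
                     [[1, 1, 0, 1, 0]] * 6)
        tree = build_tree(d, PCTParams())
        out = tree.predict({"x": 99.0})
        assert out.tolist() == [1, 1, 0, 1, 0]

    def test_missing_value_follows_majority_branch(self, toy_hierarchy):
        rows = [[1, 0, 0, 0, 0]] * 8 + [[0, 0, 0, 0, 1]] * 4
        d = _dataset(toy_hierarchy, {"x": [0] * 8 + [1] * 4}, rows)
        tree = build_tree(d, PCTParams(min_leaf=2, f_test_significance=0.125))
        assert not tree.root.is_leaf
        # the no-branch (x <= t) holds 8 of 12 examples, so missing goes there
        assert tree.root.missing_to_yes is False
        out = tree.predict({"x": float("nan")})
        assert out[0] == pytest.approx(1.0)

    def test_dataset_and_instance_paths_agree(self):
        d, _ = make_dataset(SyntheticConfig(n_classes=8, n_instances=150, seed=8))
        tree = build_tree(d, PCTParams())
        mat = tree.predict_dataset(d)
        for i in [0, 17, 149]:
            row = {a.name: d.X[a.name].iloc[i] for a in d.attributes}
            np.testing.assert_allclose(tree.predict(row), mat[i])

    def test_unknown_attribute_set_rejected(self, toy_hierarchy):
        d = _dataset(toy_hierarchy, {"x": [1, 2, 3, 4, 5, 6]},
                     [[0] * 5] * 6)
        tree = build_tree(d, PCTParams())
        bad = _dataset(toy_hierarchy, {"z": [1, 2, 3]}, [[0] * 5] * 3)
        with pytest.raises(ValueError, match="lacks"):
            tree.predict_dataset(bad)


class TestApplyThresholds:
    def test_uniform_threshold_example(self, toy_hierarchy):
        got = apply_thresholds(toy_hierarchy, [0.5, 0.45, 0.1, 0.41, 0.0], 0.4)
        assert got == {"1", "2", "2/2"}

    def test_zero_threshold_predicts_everything(self, toy_hierarchy):
        got = apply_thresholds(toy_hierarchy, [0.0] * 5, 0.0)
        assert got == set(toy_hierarchy.classes)

    def test_threshold_above_one_predicts_nothing(self, toy_hierarchy):
        assert apply_thresholds(toy_hierarchy, [1.0] * 5, 1.0 + 1e-9) == set()

    def test_ancestor_incompatible_threshold_map_rejected(self, toy_hierarchy):
        bad = {c: 0.4 for c in toy_hierarchy.classes}
        bad["2"] = 0.9  # parent stricter than child 2/2
        with pytest.raises(ValueError, match="descendant"):
            apply_thresholds(toy_hierarchy, [0.5] * 5, bad)


class TestRules:
    def test_single_leaf_rule_has_empty_antecedent(self, toy_hierarchy):
        d = _dataset(toy_hierarchy, {"x": [1, 2, 3, 4, 5, 6]},
                     [[0, 1, 0, 1, 0]] * 6)
        tree = build_tree(d, PCTParams())
        rules = extract_rules(tree, "2/2", min_score=0.5)
        assert len(rules) == 1
        assert rules[0].conditions == ()
        assert rules[0].score == 1.0

    def test_rule_count_bounded_by_leaves(self):
        d, _ = make_dataset(SyntheticConfig(n_classes=8, n_instances=200, seed=9))
        tree = build_tree(d, PCTParams())
        cls = d.hierarchy.classes[-1]
        assert len(extract_rules(tree, cls, 0.0)) <= len(tree.leaves())

    def test_rules_replay_to_their_leaf(self):
        d, _ = make_dataset(SyntheticConfig(n_classes=6, n_instances=200, seed=10))
        tree = build_tree(d, PCTParams())
        cls = d.hierarchy.classes[0]
        scores = tree.predict_dataset(d)
        for rule in extract_rules(tree, cls, min_score=0.8):
            sat = _rows_satisfying(d, rule)
            ci = d.hierarchy.class_index[cls]
            # every training row matching the antecedent reaches a leaf with
            # the rule's score for the class
            assert np.all(scores[sat, ci] >= 0.8)

    def test_printed_tree_mentions_root_test(self):
        d, _ = make_dataset(SyntheticConfig(n_classes=6, n_instances=200, seed=10))
        tree = build_tree(d, PCTParams())
        text = print_tree(tree)
        assert tree.root.test.attribute in text
        assert "leaf" in text


def _rows_satisfying(d, rule):
    mask = np.ones(d.n_instances, dtype=bool)
    for cond in rule.conditions:
        parts = cond.split()
        name = parts[0]
        x = d.X[name].to_numpy(dtype=float)
        if parts[1] == ">":
            mask &= x > float(parts[2])
        elif parts[1] == "<=":
            mask &= x <= float(parts[2])
        elif parts[1] == "=":
            mask &= x == float(parts[2])
    return np.flatnonzero(mask)
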