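"""Tests for CART growth, cost-complexity pruning, and CV subtree selection."""

import numpy as np
import pandas as pd
import pytest

from ssi_ident.claims_model import PatientEpisode
from ssi_ident.tree_classifier import (
    CartNode,
    CartTree,
    GrowthParams,
    best_split,
    cost_complexity_sequence,
    gini_impurity,
    grow_tree,
    predict_tree,
    prune_at,
    select_subtree_cv,
)

LOOSE = GrowthParams(min_split=2, min_leaf=1, max_depth=30)


def frame(x, y, name="x"):
    return pd.DataFrame({name: x, "ssi_label": y})


def training_cost(tree: CartTree, data: pd.DataFrame) -> int:
    preds, _ = tree.predict_frame(data)
    return int((preds != np.asarray(data["ssi_label"])).sum())


class TestGini:
    @pytest.mark.parametrize(
        "counts,expected", [((10, 10), 0.5), ((20, 0), 0.0), ((3, 1), 0.375), ((1, 3), 0.375)]
    )
    def test_hand_arithmetic(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestBestSplit:
    def test_separating_midpoint_found_by_enumeration(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0, 0, 1, 1])
        var, threshold, gain = best_split(X, y, ["x"], LOOSE)
        assert (var, threshold) == ("x", 2.5)
        assert gain == pytest.approx(0.5)

    def test_pure_node_has_no_split(self):
        X = np.array([[1.0], [2.0]])
        assert best_split(X, np.array([1, 1]), ["x"], LOOSE) is None

    def test_duplicate_variable_tie_breaks_to_input_order(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        y = np.array([0, 0, 1, 1])
        var, _, _ = best_split(X, y, ["x1", "x2"], LOOSE)
        assert var == "x1"

    def test_min_leaf_rules_out_unbalanced_splits(self):
        X = np.array([[1.0], [2.0], [2.0], [2.0], [2.0], [2.0]])
        y = np.array([1, 0, 0, 0, 0, 0])
        # only candidate split isolates a single case on the left
        assert best_split(X, y, ["x"], GrowthParams(min_split=2, min_leaf=2, max_depth=5)) is None


class TestGrow:
    def test_linearly_separable_data_yields_depth_one_tree(self):
        data = frame([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [0, 0, 0, 1, 1, 1])
        tree = grow_tree(data, ["x"], LOOSE)
        assert tree.n_leaves == 2
        assert training_cost(tree, data) == 0

    def test_constant_labels_yield_single_leaf(self):
        data = frame([1.0, 2.0, 3.0], [0, 0, 0])
        tree = grow_tree(data, ["x"], LOOSE)
        assert tree.root.is_leaf

    def test_child_counts_sum_to_parent(self):
        rng = np.random.default_rng(2)
        data = pd.DataFrame(
            {"a": rng.random(200), "b": rng.random(200),
             "ssi_label": (rng.random(200) < 0.3).astype(int)}
        )
        tree = grow_tree(data, ["a", "b"], GrowthParams(min_split=10, min_leaf=5, max_depth=4))
        for node in tree.root.internal_nodes():
            assert node.left.n + node.right.n == node.n
            assert tuple(map(sum, zip(node.left.class_counts, node.right.class_counts))) == node.class_counts

    def test_each_split_never_increases_training_cost(self):
        rng = np.random.default_rng(4)
        data = pd.DataFrame(
            {"a": rng.random(300), "ssi_label": (rng.random(300) < 0.4).astype(int)}
        )
        tree = grow_tree(data, ["a"], GrowthParams(min_split=5, min_leaf=2, max_depth=8))
        for node in tree.root.internal_nodes():
            assert node.subtree_cost() <= node.resubstitution_cost

    def test_training_cost_matches_independent_tree_learner_when_fully_grown(self):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        rng = np.random.default_rng(6)
        X = rng.integers(0, 5, size=(80, 2)).astype(float)
        y = (rng.random(80) < 0.4).astype(int)
        data = pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "ssi_label": y})
        ours = grow_tree(data, ["a", "b"], LOOSE)
        ref = sklearn_tree.DecisionTreeClassifier(criterion="gini", random_state=0).fit(X, y)
        # both fully grown trees reach the irreducible training error
        assert training_cost(ours, data) == int((ref.predict(X) != y).sum())


class TestPruning:
    def test_single_internal_node_alpha_equals_root_error(self):
        data = frame([0.0, 1.0] * 5, [0, 1] * 5)
        tree = grow_tree(data, ["x"], LOOSE)
        steps = cost_complexity_sequence(tree)
        assert len(steps) == 1
        assert steps[0].alpha == pytest.approx(5.0)  # R(root)=5, R(subtree)=0, one extra leaf
        assert steps[0].n_leaves == 1

    def test_root_only_tree_has_empty_sequence(self):
        tree = grow_tree(frame([1.0, 2.0], [0, 0]), ["x"], LOOSE)
        assert cost_complexity_sequence(tree) == []

    def test_alphas_increase_and_subtrees_nest_on_random_trees(self):
        rng = np.random.default_rng(10)
        for _ in range(15):
            n = int(rng.integers(20, 60))
            data = pd.DataFrame(
                {"a": rng.random(n), "b": rng.integers(0, 4, n).astype(float),
                 "ssi_label": (rng.random(n) < 0.5).astype(int)}
            )
            tree = grow_tree(data, ["a", "b"], LOOSE)
            steps = cost_complexity_sequence(tree)
            alphas = [s.alpha for s in steps]
            leaves = [s.n_leaves for s in steps]
            assert all(a < b for a, b in zip(alphas, alphas[1:]))
            assert all(a > b for a, b in zip(leaves, leaves[1:]))
            if steps:
                assert leaves[-1] == 1
            prev_ids = {id_ for node in tree.root.internal_nodes() for id_ in [node.node_id]}
            for step in steps:
                pruned = prune_at(tree, step.alpha)
                ids = {n_.node_id for n_ in pruned.root.internal_nodes()}
                assert ids <= prev_ids  # nested subtree family
                prev_ids = ids

    def test_prune_at_zero_keeps_only_cost_free_structure(self):
        data = frame([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [0, 0, 0, 1, 1, 1])
        tree = grow_tree(data, ["x"], LOOSE)
        assert prune_at(tree, 0.0).n_leaves == 2  # separating split costs nothing to keep


class TestCvSelection:
    def test_noise_free_separable_data_retains_the_split(self):
        data = frame([float(i) for i in range(40)], [0] * 20 + [1] * 20)
        tree = select_subtree_cv(data, ["x"], GrowthParams(min_split=4, min_leaf=2, max_depth=5),
                                 v=5, seed=0)
        assert tree.n_leaves >= 2
        assert training_cost(tree, data) == 0

    def test_same_data_same_seed_is_identical(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame(
            {"a": rng.random(120), "ssi_label": (rng.random(120) < 0.3).astype(int)}
        )
        t1 = select_subtree_cv(data, ["a"], v=5, seed=3)
        t2 = select_subtree_cv(data, ["a"], v=5, seed=3)
        assert t1.to_dict() == t2.to_dict()

    def test_pure_noise_prunes_to_root_in_most_replicates(self):
        # imbalanced noise: the root (majority vote) has strictly lower
        # expected held-out cost than any split, so CV should usually keep
        # nothing (at 50/50 noise every subtree ties in expectation and the
        # minimum-cost rule picks arbitrarily)
        root_only = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            data = pd.DataFrame(
                {"a": rng.random(300), "b": rng.random(300),
                 "ssi_label": (rng.random(300) < 0.3).astype(int)}
            )
            tree = select_subtree_cv(data, ["a", "b"],
                                     GrowthParams(min_split=10, min_leaf=5, max_depth=5),
                                     v=5, seed=seed)
            root_only += int(tree.root.is_leaf)
        assert root_only > 10

    def test_fold_count_reduced_with_warning_when_a_class_is_tiny(self):
        data = frame([float(i) for i in range(20)], [0] * 17 + [1] * 3)
        with pytest.warns(UserWarning, match="folds"):
            select_subtree_cv(data, ["x"], GrowthParams(min_split=4, min_leaf=2, max_depth=3),
                              v=10, seed=0)

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            select_subtree_cv(frame([1.0, 2.0, 3.0], [0, 0, 1]), ["x"], v=2, seed=0)


class TestPredict:
    @staticmethod
    def _episode(los: float) -> PatientEpisode:
        return PatientEpisode(
            patient_id="p", age=60, sex="male", los=los, vessels_obstructed=2,
            antibiotic_types=1, antibiotic_ddd_total=3.0, cefazolin_ddd=0.0,
        )

    def test_root_only_tree_predicts_the_majority_class(self):
        root = CartNode(node_id=0, n=1000, class_counts=(976, 24))
        tree = CartTree(root=root, variables=["los"], growth_params=GrowthParams())
        assert predict_tree(tree, self._episode(60.0)).prediction == 0

    def test_leaf_probability_is_the_class_fraction(self):
        left = CartNode(node_id=1, n=5, class_counts=(5, 0))
        right = CartNode(node_id=2, n=5, class_counts=(1, 4))
        root = CartNode(node_id=0, n=10, class_counts=(6, 4), split_variable="los",
                        split_threshold=21.0, left=left, right=right)
        tree = CartTree(root=root, variables=["los"], growth_params=GrowthParams())
        result = predict_tree(tree, self._episode(50.0))
        assert result.prediction == 1
        assert result.score == pytest.approx(0.8)

    def test_threshold_equality_routes_left(self):
        left = CartNode(node_id=1, n=5, class_counts=(0, 5))
        right = CartNode(node_id=2, n=5, class_counts=(5, 0))
        root = CartNode(node_id=0, n=10, class_counts=(5, 5), split_variable="los",
                        split_threshold=21.0, left=left, right=right)
        tree = CartTree(root=root, variables=["los"], growth_params=GrowthParams())
        assert predict_tree(tree, self._episode(21.0)).prediction == 1  # left leaf

    def test_tied_leaf_predicts_non_ssi(self):
        root = CartNode(node_id=0, n=10, class_counts=(5, 5))
        tree = CartTree(root=root, variables=["los"], growth_params=GrowthParams())
        assert predict_tree(tree, self._episode(5.0)).prediction == 0

    def test_json_and_text_export_round_trip_structure(self, tmp_path):
        data = frame([1.0, 2.0, 3.0, 10.0, 11.0, 12.0], [0, 0, 0, 1, 1, 1])
        tree = grow_tree(data, ["x"], LOOSE)
        tree.to_json(tmp_path / "tree.json")
        import json

        d = json.loads((tmp_path / "tree.json").read_text())
        assert d["root"]["split_variable"] == "x"
        assert "x <= " in tree.to_text()
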