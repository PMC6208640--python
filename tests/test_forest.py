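import json

import numpy as np
import pytest

from conftest import random_binary_dataset
from traitforest.forest import (DecisionTree, ForestModel, balanced_accuracy,
                                balanced_accuracy_from_labels, gini_impurity,
                                grow_tree, load_model, model_from_dict,
                                model_to_dict, oob_votes,
                                permutation_importance, roc_auc, save_model,
                                train_forest)


def brute_force_auc(scores, labels):
    """Concordant-pair (Mann-Whitney) statistic, ties counted half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                conc += 1
            elif p == n:
                ties += 1
    return (2 * conc + ties) / (2.0 * len(pos) * len(neg))


def make_stump(feature, counts_root, counts_left, counts_right, n_train,
               in_bag=None):
    if in_bag is None:
        in_bag = np.ones(n_train, dtype=np.int32)
    return DecisionTree(
        np.array([feature, -1, -1], dtype=np.int32),
        np.array([1, -1, -1], dtype=np.int32),
        np.array([2, -1, -1], dtype=np.int32),
        np.array([counts_root, counts_left, counts_right], dtype=np.int64),
        np.asarray(in_bag, dtype=np.int32))


def make_leaf(counts, n_train, in_bag=None):
    if in_bag is None:
        in_bag = np.ones(n_train, dtype=np.int32)
    return DecisionTree(np.array([-1], dtype=np.int32),
                        np.array([-1], dtype=np.int32),
                        np.array([-1], dtype=np.int32),
                        np.array([counts], dtype=np.int64),
                        np.asarray(in_bag, dtype=np.int32))


class TestGini:
    @pytest.mark.parametrize("counts, expected", [
        ((5, 5), 0.5), ((10, 0), 0.0), ((3, 1), 0.375)])
    def test_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_empty_node(self):
        with pytest.raises(ValueError):
            gini_impurity((0, 0))


class TestGrowTree:
    def test_pure_labels_give_single_leaf(self):
        X = np.array([[0, 1], [1, 0], [1, 1]], dtype=np.int8)
        y = np.array([1, 1, 1], dtype=np.int8)
        t = grow_tree(X, y, np.arange(3), m_try=2,
                      rng=np.random.default_rng(0))
        assert t.n_nodes == 1 and t.feature[0] == -1

    def test_perfect_single_feature_split(self):
        # labels follow feature 2 exactly; exhaustive check over features
        # confirms it is the unique zero-impurity split
        X = np.array([[0, 0, 0, 1], [1, 1, 0, 0], [0, 1, 1, 1], [1, 0, 1, 0]],
                     dtype=np.int8)
        y = X[:, 2].copy()
        for f in range(4):
            separates = all(len(set(y[X[:, f] == v])) <= 1 for v in (0, 1))
            assert separates == (f == 2)
        t = grow_tree(X, y, np.arange(4), m_try=4,
                      rng=np.random.default_rng(0))
        assert t.feature[0] == 2
        for child in (t.left[0], t.right[0]):
            c0, c1 = t.counts[child]
            assert c0 == 0 or c1 == 0

    def test_in_bag_accuracy_is_perfect_with_full_mtry(self):
        rng = np.random.default_rng(5)
        X, y = random_binary_dataset(80, 8, rng, rule="linear")
        ids = np.arange(80)
        t = grow_tree(X, y, ids, m_try=8, rng=np.random.default_rng(1),
                      min_node=1)
        assert np.array_equal(t.votes(X), y)

    def test_counts_partition_parent(self, small_forest):
        for t in small_forest.trees:
            for node in range(t.n_nodes):
                if t.feature[node] >= 0:
                    np.testing.assert_array_equal(
                        t.counts[node],
                        t.counts[t.left[node]] + t.counts[t.right[node]])

    def test_empty_in_bag_rejected(self):
        with pytest.raises(ValueError):
            grow_tree(np.zeros((2, 2), dtype=np.int8),
                      np.array([0, 1], dtype=np.int8), np.array([], dtype=int),
                      1, np.random.default_rng(0))


class TestTrainForest:
    def test_single_tree(self):
        rng = np.random.default_rng(0)
        X, y = random_binary_dataset(30, 5, rng)
        model = train_forest((X, y), n_trees=1, seed=0)
        assert model.n_trees == 1

    def test_same_seed_identical_trees(self):
        rng = np.random.default_rng(2)
        X, y = random_binary_dataset(60, 6, rng)
        m1 = train_forest((X, y), n_trees=20, seed=9)
        m2 = train_forest((X, y), n_trees=20, seed=9)
        for a, b in zip(m1.trees, m2.trees):
            np.testing.assert_array_equal(a.feature, b.feature)
            np.testing.assert_array_equal(a.counts, b.counts)
            np.testing.assert_array_equal(a.in_bag_count, b.in_bag_count)

    def test_growing_the_forest_keeps_early_trees(self):
        rng = np.random.default_rng(3)
        X, y = random_binary_dataset(40, 6, rng)
        small = train_forest((X, y), n_trees=5, seed=4)
        big = train_forest((X, y), n_trees=15, seed=4)
        for a, b in zip(small.trees, big.trees):
            np.testing.assert_array_equal(a.feature, b.feature)
            np.testing.assert_array_equal(a.in_bag_count, b.in_bag_count)

    def test_single_class_rejected(self):
        X = np.zeros((10, 3), dtype=np.int8)
        y = np.ones(10, dtype=np.int8)
        with pytest.raises(ValueError, match="single class"):
            train_forest((X, y), n_trees=5)

    def test_separable_data_high_oob_accuracy(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 2, size=(250, 12)).astype(np.int8)
        y = X[:, 3].copy()  # linearly separable by one feature
        model = train_forest((X, y), n_trees=500, seed=1)
        votes = oob_votes(model, (X, y))
        mask = votes.counted_mask()
        ba = balanced_accuracy_from_labels(y[mask], votes.predicted[mask])
        assert ba >= 0.95


class TestOobVotes:
    def test_in_bag_sample_flagged_with_one_tree(self):
        rng = np.random.default_rng(1)
        X, y = random_binary_dataset(40, 5, rng)
        model = train_forest((X, y), n_trees=1, seed=0)
        votes = oob_votes(model, (X, y))
        in_bag = model.trees[0].in_bag_count > 0
        assert np.all(votes.counted[in_bag] == 0)
        assert np.all(np.isnan(votes.fraction[in_bag]))
        assert np.all(votes.predicted[in_bag] == -1)

    def test_counted_fraction_near_e_inverse(self):
        rng = np.random.default_rng(2)
        X, y = random_binary_dataset(200, 4, rng)
        model = train_forest((X, y), n_trees=400, seed=3)
        votes = oob_votes(model, (X, y))
        assert abs(votes.counted.mean() / 400 - np.exp(-1)) < 0.03

    def test_unanimous_stumps_vote_one(self):
        # every tree's reachable leaves hold positive majorities
        trees = [make_stump(0, (2, 8), (1, 4), (1, 4), n_train=4,
                            in_bag=[1, 0, 1, 0]) for _ in range(5)]
        model = ForestModel(trees, 1, ("f0", "f1"), ("neg", "pos"), 0,
                            n_train=4)
        X = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=np.int8)
        votes = oob_votes(model, (X, np.array([0, 1, 0, 1], dtype=np.int8)))
        counted = votes.counted_mask()
        assert counted.any()
        assert np.all(votes.fraction[counted] == 1.0)


class TestPredict:
    def test_tie_resolves_negative(self):
        t_pos = make_stump(0, (4, 6), (2, 3), (2, 3), n_train=2)
        t_neg = make_stump(0, (6, 4), (3, 2), (3, 2), n_train=2)
        model = ForestModel([t_pos, t_neg], 1, ("f0",), ("neg", "pos"), 0,
                            n_train=2)
        cls, frac = model.predict_one(np.array([1], dtype=np.int8))
        assert frac == 0.5
        assert cls == 0

    def test_all_positive_votes(self):
        trees = [make_leaf((1, 9), n_train=2) for _ in range(7)]
        model = ForestModel(trees, 1, ("f0",), ("neg", "pos"), 0, n_train=2)
        cls, frac = model.predict_one(np.array([0], dtype=np.int8))
        assert (cls, frac) == (1, 1.0)

    def test_single_tree_matches_leaf_majority(self):
        rng = np.random.default_rng(4)
        X, y = random_binary_dataset(30, 4, rng)
        model = train_forest((X, y), n_trees=1, seed=2)
        t = model.trees[0]
        leaves = t.apply(X)
        expected = (t.counts[leaves, 1] > t.counts[leaves, 0]).astype(int)
        np.testing.assert_array_equal(model.predict(X)[0], expected)

    def test_width_mismatch(self, small_forest):
        with pytest.raises(ValueError, match="length"):
            small_forest.predict(np.zeros((1, 3), dtype=np.int8))


class TestBalancedAccuracy:
    @pytest.mark.parametrize("cm, expected", [
        ((10, 0, 10, 0), 1.0), ((90, 10, 60, 40), 0.75), ((0, 10, 0, 10), 0.0)])
    def test_values(self, cm, expected):
        assert balanced_accuracy(*cm) == pytest.approx(expected)

    def test_absent_class(self):
        with pytest.raises(ValueError):
            balanced_accuracy(0, 0, 5, 5)


class TestRocAuc:
    def test_perfectly_ordered(self):
        assert roc_auc(np.array([.9, .8, .2, .1]), [1, 1, 0, 0]).auc == 1.0

    def test_label_inversion_symmetry(self):
        rng = np.random.default_rng(0)
        votes = rng.uniform(size=30)
        labels = rng.integers(0, 2, size=30)
        a = roc_auc(votes, labels).auc
        b = roc_auc(votes, 1 - labels).auc
        assert a + b == pytest.approx(1.0)

    def test_six_sample_concordant_pairs(self):
        votes = [.9, .8, .7, .4, .3, .1]
        labels = [1, 1, 0, 1, 0, 0]
        assert roc_auc(votes, labels).auc == pytest.approx(8 / 9)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            n = int(rng.integers(4, 21))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels).auc == brute_force_auc(scores, labels)


class TestPermutationImportance:
    def test_unused_feature_scores_zero(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 2, size=(60, 4)).astype(np.int8)
        X[:, 3] = 0  # constant -> never a valid split
        y = X[:, 0].copy()
        model = train_forest((X, y), n_trees=30, seed=1)
        imp = permutation_importance(model, (X, y), seed=0)
        assert imp[3] == 0.0

    def test_predictive_feature_positive(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 2, size=(100, 2)).astype(np.int8)
        y = X[:, 0].copy()  # feature 0 = signal, feature 1 = noise
        model = train_forest((X, y), n_trees=50, seed=2)
        imp = permutation_importance(model, (X, y), seed=0)
        assert imp[0] > 0
        assert imp[0] > imp[1]

    def test_deterministic(self, small_forest, small_dataset):
        a = permutation_importance(small_forest, small_dataset, seed=5)
        b = permutation_importance(small_forest, small_dataset, seed=5)
        np.testing.assert_array_equal(a, b)


class TestSerialization:
    def test_round_trip_bit_exact(self, small_forest, tmp_path):
        p = tmp_path / "model.json"
        save_model(small_forest, p)
        back = load_model(p)
        assert json.dumps(model_to_dict(back)) == json.dumps(
            model_to_dict(small_forest))
        x = np.zeros(small_forest.n_features, dtype=np.int8)
        assert back.predict_one(x) == small_forest.predict_one(x)

    def test_rejects_foreign_payload(self):
        with pytest.raises(ValueError):
            model_from_dict({"format": "something-else"})


class TestAgainstReferenceImplementation:
    def test_oob_error_close_to_sklearn(self):
        sklearn_ensemble = pytest.importorskip("sklearn.ensemble")
        rng = np.random.default_rng(10)
        X = rng.integers(0, 2, size=(300, 10)).astype(np.int8)
        y = ((X[:, 0] & X[:, 1]) | X[:, 2]).astype(np.int8)
        flip = rng.uniform(size=300) < 0.1
        y = np.where(flip, 1 - y, y).astype(np.int8)
        ours = train_forest((X, y), n_trees=300, seed=0)
        votes = oob_votes(ours, (X, y))
        mask = votes.counted_mask()
        our_err = float(np.mean(votes.predicted[mask] != y[mask]))
        ref = sklearn_ensemble.RandomForestClassifier(
            n_estimators=300, max_features="sqrt", oob_score=True,
            random_state=0).fit(X, y)
        ref_err = 1.0 - ref.oob_score_
        assert abs(our_err - ref_err) <= 0.05
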