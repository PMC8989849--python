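"""C4.5 tree: information measures, split search vs brute force, estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import emoeeg as e
from emoeeg.tree import C45TreeClassifier, DecisionNode, build_tree, predict_one

from .oracles import best_split_bruteforce, entropy_bits, gain_stats

TOY_X = np.array([[1.0], [2.0], [3.0], [4.0]])
TOY_Y = np.array(["+", "+", "-", "-"], dtype=object)


class TestInformationMeasures:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["+", "+", "-", "-"], 1.0),
            (["+", "+", "+", "+"], 0.0),
            (["+", "+", "+", "-"], 0.8112781244591328),
        ],
    )
    def test_class_entropy_values(self, labels, expected):
        assert e.class_entropy(labels) == pytest.approx(expected, abs=1e-12)

    def test_class_entropy_matches_scipy(self, rng):
        from scipy.stats import entropy as scipy_entropy

        labels = rng.choice(list("abc"), size=60)
        _, counts = np.unique(labels, return_counts=True)
        assert e.class_entropy(labels) == pytest.approx(
            scipy_entropy(counts, base=2), abs=1e-12
        )

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            e.class_entropy([])

    def test_perfect_partition_entropy_zero(self):
        assert e.partition_entropy(TOY_X[:, 0], TOY_Y, 2.5) == 0.0

    def test_one_sided_partition_equals_class_entropy(self):
        assert e.partition_entropy(TOY_X[:, 0], TOY_Y, 99.0) == pytest.approx(
            e.class_entropy(TOY_Y)
        )

    @pytest.mark.parametrize(
        "threshold,expected",
        [(2.5, 1.0), (99.0, 0.0), (3.5, 0.8112781244591328)],
    )
    def test_split_info_values(self, threshold, expected):
        assert e.split_info(TOY_X[:, 0], threshold) == pytest.approx(
            expected, abs=1e-12
        )

    def test_gain_ratio_on_perfect_split(self):
        cand = e.gain_ratio(TOY_X[:, 0], TOY_Y, 2.5, attribute="x")
        assert cand.gain == pytest.approx(1.0, abs=1e-12)
        assert cand.split_info == pytest.approx(1.0, abs=1e-12)
        assert cand.gain_ratio == pytest.approx(1.0, abs=1e-12)

    def test_one_sided_candidate_marked_invalid(self):
        cand = e.gain_ratio(TOY_X[:, 0], TOY_Y, 99.0)
        assert not cand.valid

    def test_uninformative_attribute_has_zero_gain(self):
        values = np.array([1.0, 2.0, 1.0, 2.0])
        cand = e.gain_ratio(values, TOY_Y, 1.5)
        assert cand.gain == pytest.approx(0.0, abs=1e-12)


class TestCandidateThresholds:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 2, 4], [1.5, 3.0]), ([5, 5, 5], []), ([3, 1, 2, 2], [1.5, 2.5])],
    )
    def test_midpoints(self, values, expected):
        np.testing.assert_allclose(e.candidate_thresholds(values), expected)


class TestBestSplit:
    def test_finds_perfect_split(self):
        cand = e.best_split(TOY_X, TOY_Y, ["x"])
        assert cand.attribute == "x" and cand.threshold == 2.5

    def test_pure_labels_give_none(self):
        assert e.best_split(TOY_X, np.array(["+"] * 4, dtype=object), ["x"]) is None

    def test_chain_consistency_against_direct_formulas(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.choice(["a", "b"], size=20)
        cand = e.best_split(X, y, ["a0", "a1", "a2"])
        if cand is None:
            return
        g, si, ratio = gain_stats(X[:, cand.feature_index], y, cand.threshold)
        assert cand.gain == pytest.approx(g, abs=1e-12)
        assert cand.split_info == pytest.approx(si, abs=1e-12)
        assert cand.gain_ratio == pytest.approx(ratio, abs=1e-12)

    @given(st.data())
    @settings(max_examples=60)
    def test_equals_bruteforce_argmax(self, data):
        n = data.draw(st.integers(2, 12))
        n_feat = data.draw(st.integers(1, 3))
        X = np.array(
            [
                [data.draw(st.integers(0, 4)) for _ in range(n_feat)]
                for _ in range(n)
            ],
            dtype=float,
        )
        y = np.array([data.draw(st.sampled_from("pq")) for _ in range(n)],
                     dtype=object)
        names = ["a", "b", "c"][:n_feat]
        got = e.best_split(X, y, names)
        want = best_split_bruteforce(X.tolist(), y.tolist(), names)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert got.gain_ratio == pytest.approx(want[0], abs=1e-12)
            assert (got.attribute, got.threshold) == (want[1], want[2])


class TestBuildAndPredict:
    def test_toy_set_builds_depth_one_stump(self):
        root = build_tree(TOY_X, TOY_Y, ["x"])
        assert root.depth() == 1
        assert predict_one(root, {"x": 1.0}) == "+"
        assert predict_one(root, {"x": 4.0}) == "-"

    def test_single_class_dataset_is_single_leaf(self):
        root = build_tree(TOY_X, np.array(["+"] * 4, dtype=object), ["x"])
        assert root.is_leaf and root.label == "+"

    def test_xor_pattern_separated_at_depth_two(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array(["a", "b", "b", "a"], dtype=object)
        clf = C45TreeClassifier().fit(X, y)
        assert clf.score(X, y) == 1.0
        assert clf.tree_.depth() == 2

    def test_missing_attribute_is_an_error(self):
        root = build_tree(TOY_X, TOY_Y, ["x"])
        with pytest.raises(KeyError, match="x"):
            predict_one(root, {"z": 1.0})

    def test_training_accuracy_is_perfect_on_consistent_data(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.choice(["happy", "angry"], size=60)
        clf = C45TreeClassifier().fit(X, y)
        assert clf.score(X, y) == 1.0

    def test_construction_is_deterministic(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.choice(["a", "b"], size=40)
        t1 = C45TreeClassifier().fit(X, y).tree_.to_dict()
        t2 = C45TreeClassifier().fit(X, y).tree_.to_dict()
        assert t1 == t2

    def test_predict_proba_reflects_leaf_counts(self):
        X = np.array([[0.0], [0.0], [0.0], [0.0], [1.0]])
        y = np.array(["happy", "happy", "happy", "angry", "angry"], dtype=object)
        clf = C45TreeClassifier(max_depth=0).fit(X, y)  # single leaf
        proba = clf.predict_proba(np.array([[0.5]]))
        np.testing.assert_allclose(proba, [[0.4, 0.6]])  # classes_ sorted
        assert list(clf.classes_) == ["angry", "happy"]

    def test_max_depth_limits_tree(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.choice(["a", "b"], size=50)
        clf = C45TreeClassifier(max_depth=2).fit(X, y)
        assert clf.tree_.depth() <= 2

    def test_pruning_never_increases_leaf_count(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.choice(["a", "b"], size=50)
        full = C45TreeClassifier().fit(X, y)
        pruned = C45TreeClassifier(prune=True).fit(X, y)
        assert pruned.tree_.n_leaves() <= full.tree_.n_leaves()

    def test_dataframe_input_sets_feature_names(self, ei_table):
        from emoeeg.features import split_feature_frame

        X, y = split_feature_frame(ei_table)
        clf = C45TreeClassifier().fit(X, y)
        assert clf.feature_names_in_ == list(X.columns)
        assert clf.tree_.attribute in X.columns

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            C45TreeClassifier().predict(TOY_X)

    def test_serialization_roundtrip(self):
        root = build_tree(TOY_X, TOY_Y, ["x"])
        again = DecisionNode.from_dict(root.to_dict())
        assert again.to_dict() == root.to_dict()
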