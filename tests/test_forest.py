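"""Improved random forest: Pearson penalty, bootstrap, weighted voting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emoeeg as e
from emoeeg.features import split_feature_frame
from emoeeg.forest import (
    ImprovedRandomForestClassifier,
    attribute_redundancy,
    bootstrap_sample,
    weighted_vote,
)
from emoeeg.tree import C45TreeClassifier

from .oracles import all_vote_profiles, majority_vote


class TestPearson:
    def test_identical_series_give_one(self):
        x = np.array([1.0, 2.0, 5.0])
        assert e.pearson(x, x) == 1.0

    def test_negated_series_give_minus_one(self):
        x = np.array([1.0, 2.0, 5.0])
        assert e.pearson(x, -x) == -1.0

    def test_printed_formula_value(self):
        assert e.pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.98198, abs=5e-6)

    def test_matches_scipy(self, rng):
        from scipy.stats import pearsonr

        x, y = rng.normal(size=100), rng.normal(size=100)
        assert e.pearson(x, y) == pytest.approx(pearsonr(x, y)[0], abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            e.pearson([1, 2], [1, 2, 3])

    def test_zero_variance_defined_as_zero(self):
        assert e.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) == 0.0


class TestRedundancy:
    def test_duplicated_attribute_gives_one(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, x])
        assert attribute_redundancy(X, 0, [1]) == pytest.approx(1.0)

    def test_independent_attribute_near_zero(self):
        vals = []
        for s in range(20):
            r = np.random.default_rng(s)
            X = np.column_stack([r.normal(size=1000), r.normal(size=1000)])
            vals.append(attribute_redundancy(X, 0, [1]))
        assert np.mean(vals) < 0.1

    def test_empty_reference_set_gives_zero(self, rng):
        X = rng.normal(size=(10, 2))
        assert attribute_redundancy(X, 0, []) == 0.0
        assert attribute_redundancy(X, 0, [0]) == 0.0  # self excluded


class TestImprovedGainRatio:
    def test_a_zero_reduces_to_plain_ratio(self):
        assert e.improved_gain_ratio(0.7, 0.9, 0.0, 0.5) == 0.7 / 0.9

    def test_printed_arithmetic(self):
        assert e.improved_gain_ratio(1.0, 1.0, 1.0, 1.0) == 0.5

    def test_monotone_decreasing_in_redundancy(self):
        lo = e.improved_gain_ratio(1.0, 1.0, 1.0, 0.2)
        hi = e.improved_gain_ratio(1.0, 1.0, 1.0, 0.8)
        assert lo > hi

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            e.improved_gain_ratio(1.0, 0.0, 1.0, 0.0)


class TestBootstrap:
    def test_single_row_has_empty_oob(self, rng):
        in_bag, oob = bootstrap_sample(1, rng)
        assert list(in_bag) == [0] and oob.size == 0

    def test_oob_fraction_near_one_over_e(self):
        fractions = [
            bootstrap_sample(1000, np.random.default_rng(s))[1].size / 1000
            for s in range(200)
        ]
        assert np.mean(fractions) == pytest.approx(0.368, abs=0.01)

    def test_reproducible_given_seed(self):
        a, _ = bootstrap_sample(50, np.random.default_rng(9))
        b, _ = bootstrap_sample(50, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_oob_is_complement_of_in_bag(self, rng):
        in_bag, oob = bootstrap_sample(100, rng)
        assert in_bag.size == 100
        assert set(in_bag) | set(oob) == set(range(100))
        assert set(in_bag) & set(oob) == set()


class TestWeightedVote:
    @pytest.mark.parametrize(
        "preds,weights,expected",
        [
            (("happy", "happy", "angry"), (0.5, 0.5, 0.9), "happy"),
            (("happy", "angry"), (0.3, 0.8), "angry"),
            (("happy", "angry"), (0.5, 0.5), "angry"),  # tie -> lexicographic
        ],
    )
    def test_vote_arithmetic(self, preds, weights, expected):
        assert weighted_vote(preds, weights) == expected

    def test_uniform_weights_reduce_to_majority_exhaustive(self):
        for profile in all_vote_profiles(("angry", "happy"), max_trees=5):
            assert weighted_vote(profile, np.ones(len(profile))) == majority_vote(
                profile
            )

    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=9))
    @settings(max_examples=200)
    def test_uniform_weights_reduce_to_majority_randomized(self, profile):
        assert weighted_vote(profile, np.ones(len(profile))) == majority_vote(profile)

    def test_shares_sum_to_one(self):
        _, shares = weighted_vote(
            ("a", "b", "a"), (0.2, 0.3, 0.5), return_shares=True
        )
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_empty_vote_rejected(self):
        with pytest.raises(ValueError, match="zero trees"):
            weighted_vote([], [])


def _tree_dicts(forest):
    return [member.tree.to_dict() for member in forest.estimators_]


class TestForest:
    def test_single_tree_identity_bag_reduces_to_c45(self, ei_table):
        X, y = split_feature_frame(ei_table)
        forest = ImprovedRandomForestClassifier(
            n_estimators=1,
            max_features=None,
            redundancy_weight=0.0,
            bootstrap=False,
            random_state=0,
        ).fit(X, y)
        tree = C45TreeClassifier().fit(X, y)
        np.testing.assert_array_equal(forest.predict(X), tree.predict(X))
        assert _tree_dicts(forest)[0] == tree.tree_.to_dict()

    def test_weights_within_unit_interval(self, ei_table):
        X, y = split_feature_frame(ei_table)
        forest = ImprovedRandomForestClassifier(
            n_estimators=20, random_state=1
        ).fit(X, y)
        assert all(0.0 <= m.weight <= 1.0 for m in forest.estimators_)

    def test_a_zero_matches_plain_criterion_node_for_node(self, ei_table):
        X, y = split_feature_frame(ei_table)
        improved = ImprovedRandomForestClassifier(
            n_estimators=10, redundancy_weight=0.0, random_state=7
        ).fit(X, y)
        plain = ImprovedRandomForestClassifier(
            n_estimators=10, split_criterion="plain", random_state=7
        ).fit(X, y)
        assert _tree_dicts(improved) == _tree_dicts(plain)

    def test_redundancy_penalty_discourages_duplicate_attributes(self):
        """With an informative attribute, its exact duplicate, and a weaker
        independent attribute, the penalized criterion picks the duplicated
        pair less often than plain gain ratio over seeded node-level trials."""
        from emoeeg.forest import _abs_correlation_matrix
        from emoeeg.tree import best_split

        picks = {"plain": 0, "improved": 0}
        n = 40
        for s in range(200):
            rng = np.random.default_rng(s)
            y = np.array(["a"] * (n // 2) + ["b"] * (n // 2), dtype=object)
            strong = (y == "a") * 1.0 + rng.normal(0, 0.35, n)
            weak = (y == "a") * 1.0 + rng.normal(0, 0.8, n)
            X = np.column_stack([strong, strong, weak])
            names = ["dup1", "dup2", "weak"]
            R = _abs_correlation_matrix(X)
            red = {
                j: float(np.mean([R[j, k] for k in range(3) if k != j]))
                for j in range(3)
            }
            for mode in ("plain", "improved"):
                cand = best_split(
                    X, y, names, mode=mode, a=1.0,
                    redundancy=red if mode == "improved" else None,
                )
                if cand is not None and cand.attribute.startswith("dup"):
                    picks[mode] += 1
        assert picks["improved"] < picks["plain"]

    def test_high_accuracy_on_separable_features(self, ei_table):
        X, y = split_feature_frame(ei_table)
        train, test = slice(0, 40), slice(40, 80)
        forest = ImprovedRandomForestClassifier(
            n_estimators=50, random_state=3
        ).fit(X.iloc[train], y.iloc[train])
        assert forest.score(X.iloc[test], y.iloc[test]) >= 0.9

    def test_competitive_with_sklearn_forest(self, ei_table):
        from sklearn.ensemble import RandomForestClassifier

        X, y = split_feature_frame(ei_table)
        train, test = slice(0, 40), slice(40, 80)
        ours = ImprovedRandomForestClassifier(n_estimators=100, random_state=0)
        ours.fit(X.iloc[train], y.iloc[train])
        ref = RandomForestClassifier(n_estimators=100, random_state=0)
        ref.fit(X.iloc[train], y.iloc[train])
        ours_acc = ours.score(X.iloc[test], y.iloc[test])
        ref_acc = float(np.mean(ref.predict(X.iloc[test]) == y.iloc[test]))
        assert ours_acc >= ref_acc - 0.1

    def test_prediction_deterministic_after_fit(self, ei_table):
        X, y = split_feature_frame(ei_table)
        forest = ImprovedRandomForestClassifier(
            n_estimators=15, random_state=2
        ).fit(X, y)
        np.testing.assert_array_equal(forest.predict(X), forest.predict(X))

    def test_refit_with_same_seed_is_bit_reproducible(self, ei_table):
        X, y = split_feature_frame(ei_table)
        f1 = ImprovedRandomForestClassifier(n_estimators=8, random_state=5).fit(X, y)
        f2 = ImprovedRandomForestClassifier(n_estimators=8, random_state=5).fit(X, y)
        assert _tree_dicts(f1) == _tree_dicts(f2)
        assert [m.weight for m in f1.estimators_] == [m.weight for m in f2.estimators_]

    def test_m_try_exceeding_features_rejected(self, ei_table):
        X, y = split_feature_frame(ei_table)
        with pytest.raises(ValueError, match="max_features"):
            ImprovedRandomForestClassifier(max_features=10).fit(X, y)

    def test_proba_columns_follow_classes(self, ei_table):
        X, y = split_feature_frame(ei_table)
        forest = ImprovedRandomForestClassifier(
            n_estimators=10, random_state=0
        ).fit(X, y)
        proba = forest.predict_proba(X.iloc[:5])
        assert proba.shape == (5, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        preds = forest.predict(X.iloc[:5])
        np.testing.assert_array_equal(
            preds, forest.classes_[np.argmax(proba, axis=1)]
        )
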