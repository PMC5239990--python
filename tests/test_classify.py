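"""C4.5-style trees and the AdaBoost.M1 ensemble."""

import math

import numpy as np
import pandas as pd
import pytest

from roughrelief.classify import BoostedC45, C45Tree, boost, predict_score, train_tree
from roughrelief.synthetic import SyntheticSpec, make_table


def entropy(counts):
    total = sum(counts)
    return -sum(c / total * math.log2(c / total) for c in counts if c > 0)


def gain_ratio_oracle(values, labels):
    """Exhaustive gain ratio of a multiway split on a nominal attribute."""
    base = entropy([labels.count(c) for c in set(labels)])
    groups = {}
    for v, c in zip(values, labels):
        groups.setdefault(v, []).append(c)
    n = len(labels)
    cond = sum(
        len(g) / n * entropy([g.count(c) for c in set(g)]) for g in groups.values()
    )
    split_info = entropy([len(g) for g in groups.values()])
    gain = base - cond
    return gain, (gain / split_info if split_info > 0 else float("nan"))


class TestTree:
    def test_separable_attribute_gives_depth_one_zero_error(self):
        X = pd.DataFrame({"f": pd.Series([0, 0, 1, 1] * 5, dtype=object),
                          "junk": pd.Series([0, 1] * 10, dtype=object)})
        y = ["a", "a", "b", "b"] * 5
        tree = C45Tree(feature_kinds={"f": "nominal", "junk": "nominal"}).fit(X, y)
        assert tree.tree_.depth() == 1
        assert tree.tree_.attribute == "f"
        assert (tree.predict(X) == np.array(y, dtype=object)).all()

    def test_split_matches_gain_ratio_oracle(self):
        # 8-row toy table: the builder must pick the attribute with the
        # larger gain ratio among those with above-average gain
        X = pd.DataFrame({
            "a": pd.Series(["p", "p", "p", "q", "q", "q", "r", "r"], dtype=object),
            "b": pd.Series(["u", "v", "u", "v", "u", "v", "u", "v"], dtype=object),
        })
        y = ["+", "+", "+", "-", "-", "-", "+", "-"]
        scores = {}
        gains = {}
        for col in X.columns:
            g, gr = gain_ratio_oracle(X[col].tolist(), y)
            gains[col], scores[col] = g, gr
        avg = sum(gains.values()) / len(gains)
        eligible = [c for c in X.columns if gains[c] >= avg - 1e-12]
        expected = max(eligible, key=lambda c: scores[c])
        tree = C45Tree(feature_kinds={"a": "nominal", "b": "nominal"}).fit(X, y)
        assert tree.tree_.attribute == expected

    def test_threshold_split_on_numeric(self):
        X = pd.DataFrame({"v": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]})
        y = ["lo"] * 3 + ["hi"] * 3
        tree = C45Tree(feature_kinds={"v": "real"}).fit(X, y)
        assert tree.tree_.threshold == pytest.approx(6.5)
        assert (tree.predict(pd.DataFrame({"v": [0.0, 100.0]}))
                == np.array(["lo", "hi"], dtype=object)).all()

    def test_weight_scale_invariance(self):
        table, _ = make_table(SyntheticSpec(n_objects=80, flip_noise=0.1, seed=3))
        t1 = train_tree(table, instance_weights=np.ones(80))
        t2 = train_tree(table, instance_weights=np.full(80, 2.0))
        X = table.data[table.condition_attributes]
        assert (t1.predict(X) == t2.predict(X)).all()
        assert t1.tree_.n_leaves() == t2.tree_.n_leaves()

    def test_duplication_with_halved_weights_is_invariant(self):
        # weights are rescaled to whole-instance units internally, so the
        # duplicated table counts each original instance twice; the leaf
        # threshold must be stated in the same units for exact invariance
        table, _ = make_table(SyntheticSpec(n_objects=60, flip_noise=0.1, seed=5))
        X = table.data[table.condition_attributes]
        y = table.decision_values()
        t1 = C45Tree(feature_kinds=dict(table.kinds), min_leaf_weight=2.0).fit(X, y)
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = np.concatenate([y, y])
        t2 = C45Tree(feature_kinds=dict(table.kinds), min_leaf_weight=4.0).fit(
            X2, y2, sample_weight=np.full(120, 0.5)
        )
        assert (t1.predict(X) == t2.predict(X)).all()
        assert t1.tree_.n_leaves() == t2.tree_.n_leaves()

    def test_mixed_labels_on_identical_rows_yield_majority_leaf(self):
        X = pd.DataFrame({"f": pd.Series([0, 0, 0], dtype=object)})
        tree = C45Tree(feature_kinds={"f": "nominal"}).fit(X, ["a", "a", "b"])
        assert tree.tree_.is_leaf
        assert tree.tree_.label == "a"

    def test_negative_weights_rejected(self):
        X = pd.DataFrame({"f": pd.Series([0, 1], dtype=object)})
        with pytest.raises(ValueError):
            C45Tree().fit(X, ["a", "b"], sample_weight=[-1.0, 1.0])


class TestBoost:
    def test_separable_data_single_capped_tree(self):
        table, _ = make_table(SyntheticSpec(n_objects=100, flip_noise=0.0, seed=1))
        model = boost(table, k=10, seed=0)
        assert model.n_effective_ == 1
        assert model.estimators_[0][1] >= 10.0
        X = table.data[table.condition_attributes]
        assert (model.predict(X) == table.decision_values()).all()

    def test_k_must_be_positive(self):
        table, _ = make_table(SyntheticSpec(n_objects=40, seed=2))
        with pytest.raises(ValueError):
            boost(table, k=0)

    def test_deterministic_given_seed(self):
        table, _ = make_table(SyntheticSpec(n_objects=120, flip_noise=0.15, seed=7))
        te, _ = make_table(SyntheticSpec(n_objects=50, flip_noise=0.15, seed=8))
        Xt = te.data[te.condition_attributes]
        m1 = boost(table, k=15, seed=3)
        m2 = boost(table, k=15, seed=3)
        assert [a for _, a in m1.estimators_] == [a for _, a in m2.estimators_]
        assert (m1.predict(Xt) == m2.predict(Xt)).all()
        assert m1.decision_function(Xt).tolist() == m2.decision_function(Xt).tolist()

    def test_ensemble_beats_single_tree_on_training_data(self):
        """Boosting drives training error down on most noisy datasets."""
        wins = 0
        for seed in range(20):
            table, _ = make_table(
                SyntheticSpec(n_objects=120, n_relevant=2, n_noise=2,
                              flip_noise=0.2, seed=100 + seed)
            )
            X = table.data[table.condition_attributes]
            y = table.decision_values()
            single = train_tree(table)
            ens = boost(table, k=15, seed=seed)
            acc_single = (single.predict(X) == y).mean()
            acc_ens = (ens.predict(X) == y).mean()
            if acc_ens >= acc_single:
                wins += 1
        assert wins >= 18

    def test_accepted_round_errors_below_half(self):
        table, _ = make_table(SyntheticSpec(n_objects=150, flip_noise=0.25, seed=9))
        model = boost(table, k=20, seed=1)
        # vote weight 0.5*ln((1-eps)/eps) > 0 iff eps < 0.5
        for _, alpha in model.estimators_:
            assert alpha > 0

    def test_n_effective_bounded_by_request(self):
        table, _ = make_table(SyntheticSpec(n_objects=100, flip_noise=0.2, seed=10))
        model = boost(table, k=8, seed=0)
        assert model.n_effective_ <= model.n_requested_ == 8


class TestScores:
    def fit_small(self):
        table, _ = make_table(SyntheticSpec(n_objects=100, flip_noise=0.1, seed=4))
        return table, boost(table, k=9, seed=0)

    def test_unanimous_vote_gives_unit_score(self):
        table, model = self.fit_small()
        row = table.data.iloc[0][table.condition_attributes]
        votes = {tree.predict(pd.DataFrame([dict(row)]))[0] for tree, _ in model.estimators_}
        score = predict_score(model, row)
        assert -1.0 <= score <= 1.0
        if len(votes) == 1:
            assert abs(score) == pytest.approx(1.0)

    def test_equal_opposite_votes_tie_to_positive(self):
        X = pd.DataFrame({"f": pd.Series([0, 0, 1, 1], dtype=object)})
        t_pos = C45Tree(feature_kinds={"f": "nominal"}).fit(X, [1, 1, 1, 1])
        t_neg = C45Tree(feature_kinds={"f": "nominal"}).fit(X, [0, 0, 0, 0])
        model = BoostedC45(n_estimators=2, positive=1).fit(X, [0, 1, 0, 1])
        model.estimators_ = [(t_pos, 1.0), (t_neg, 1.0)]
        score = model.decision_function(X)
        assert np.allclose(score, 0.0)
        assert (model.predict(X) == 1).all()

    def test_score_antisymmetric_under_vote_flip(self):
        table, model = self.fit_small()
        X = table.data[table.condition_attributes]
        base = model.decision_function(X)
        flipped = BoostedC45(positive=model.positive_)
        flipped.classes_ = model.classes_
        flipped.positive_ = [c for c in model.classes_ if c != model.positive_][0]
        flipped.estimators_ = model.estimators_
        assert np.allclose(model.decision_function(X), -flipped.decision_function(X))
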