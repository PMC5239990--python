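"""C4.5-style decision trees with instance weights, and AdaBoost.M1 on top.

The tree grows greedily by weighted gain ratio: nominal and binary
attributes split multiway (one child per observed category), real and
ordered attributes split on the best binary threshold among midpoints of
consecutive observed values.  Following the C4.5 convention, only
attributes whose information gain is at least the average gain of the
candidates compete on gain ratio.  Leaves predict the weighted majority
class; ties go to the class more prevalent in the whole training set, then
to the lower label.

Boosting is AdaBoost.M1 by reweighting: instance weights start uniform,
each round trains a tree, and weights are scaled by ``exp(±alpha)`` with
vote weight ``alpha = 0.5·ln((1−ε)/ε)`` for weighted error ε.  A round
with ε = 0 contributes a capped vote; a round with ε ≥ 0.5 is discarded
and the weights reset to uniform.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .table import DecisionTable, is_missing

__all__ = ["TreeNode", "C45Tree", "BoostedC45", "train_tree", "boost", "predict_score"]

log = logging.getLogger(__name__)

#: Vote weight assigned to a zero-error round.
ALPHA_CAP = 10.0


@dataclass
class TreeNode:
    """One node of a fitted tree.

    Internal nominal splits carry ``children`` keyed by category; threshold
    splits carry ``threshold`` with ``children`` keyed by ``"le"``/``"gt"``.
    ``default_key`` routes unseen or missing values to the heaviest child.
    Leaves carry ``label`` and a class→probability map.
    """

    attribute: str | None = None
    threshold: float | None = None
    children: dict = field(default_factory=dict)
    default_key: object = None
    label: object = None
    proba: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.attribute is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children.values())

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return sum(c.n_leaves() for c in self.children.values())


def _entropy(weights_per_class: np.ndarray) -> float:
    total = weights_per_class.sum()
    if total <= 0:
        return 0.0
    p = weights_per_class[weights_per_class > 0] / total
    return float(-(p * np.log2(p)).sum())


def _entropy_rows(M: np.ndarray) -> np.ndarray:
    """Entropy of each row of a (groups x classes) weight matrix."""
    tot = M.sum(axis=1, keepdims=True)
    P = np.divide(M, tot, out=np.zeros_like(M), where=tot > 0)
    L = np.zeros_like(P)
    np.log2(P, out=L, where=P > 0)
    return -(P * L).sum(axis=1)


class _TreeBuilder:
    """Grows a C4.5-style tree over integer-coded columns.

    Categorical columns are factorized once (missing gets its own code);
    numeric columns are float arrays with NaN for missing.  Nodes operate
    on index arrays into these fixed columns.
    """

    def __init__(self, attrs, kinds, columns, categories, y_codes, classes,
                 min_leaf_weight, max_depth, global_counts):
        self.attrs = attrs
        self.kinds = kinds
        self.columns = columns        # attr -> int codes or float values
        self.categories = categories  # attr -> list of original category values
        self.y_codes = y_codes
        self.classes = classes
        self.n_classes = len(classes)
        self.min_leaf_weight = min_leaf_weight
        self.max_depth = max_depth
        self.global_counts = global_counts  # per-class total training weight

    def leaf(self, idx, w) -> TreeNode:
        counts = np.bincount(self.y_codes[idx], weights=w[idx], minlength=self.n_classes)
        total = counts.sum()
        # majority; ties -> globally more prevalent class, then lower label order
        best = max(
            range(self.n_classes),
            key=lambda c: (counts[c], self.global_counts[c], -c),
        )
        proba = {
            self.classes[c]: (counts[c] / total if total > 0 else 0.0)
            for c in range(self.n_classes)
        }
        return TreeNode(label=self.classes[best], proba=proba)

    def split_candidates(self, idx, w, base, total_w):
        """Evaluate every attribute; list of (attr, gain, gain_ratio, split)."""
        out = []
        yc = self.y_codes[idx]
        wi = w[idx]
        for a in self.attrs:
            if self.kinds.get(a, "real") in ("nominal", "binary"):
                codes = self.columns[a][idx]
                n_cats = len(self.categories[a])
                M = np.zeros((n_cats, self.n_classes))
                np.add.at(M, (codes, yc), wi)
                group_w = M.sum(axis=1)
                present = group_w > 0
                if present.sum() < 2:
                    continue
                cond = float((group_w[present] / total_w * _entropy_rows(M[present])).sum())
                split_info = _entropy(group_w[present])
                gain = base - cond
                if split_info <= 0:
                    continue
                out.append((a, gain, gain / split_info, ("nominal", None)))
            else:
                vals = self.columns[a][idx]
                known = ~np.isnan(vals)
                if known.sum() < 2:
                    continue
                order = np.argsort(vals[known], kind="stable")
                v = vals[known][order]
                kyc = yc[known][order]
                kw = wi[known][order]
                onehot = np.zeros((len(v), self.n_classes))
                onehot[np.arange(len(v)), kyc] = kw
                cum = onehot.cumsum(axis=0)
                total_known = cum[-1]
                miss_w = total_w - kw.sum()
                cut = np.flatnonzero(v[:-1] != v[1:])
                if len(cut) == 0:
                    continue
                left = cum[cut]
                right = total_known - left
                lw = left.sum(axis=1)
                rw = right.sum(axis=1)
                cond = (lw / total_w) * _entropy_rows(left) + (rw / total_w) * _entropy_rows(right)
                if miss_w > 1e-12:
                    # missing values contribute the parent entropy share
                    cond = cond + (miss_w / total_w) * base
                gains = base - cond
                parts = np.stack([lw, rw, np.full_like(lw, max(miss_w, 0.0))], axis=1)
                split_info = _entropy_rows(parts)
                valid = split_info > 0
                if not valid.any():
                    continue
                gains = np.where(valid, gains, -np.inf)
                best = int(np.argmax(gains))  # ties -> lowest threshold
                thr = (v[cut[best]] + v[cut[best] + 1]) / 2.0
                out.append((a, float(gains[best]), float(gains[best] / split_info[best]),
                            ("threshold", float(thr))))
        return out

    def build(self, idx, w, depth) -> TreeNode:
        wi = w[idx]
        total_w = float(wi.sum())
        class_w = np.bincount(self.y_codes[idx], weights=wi, minlength=self.n_classes)
        if (
            (class_w > 0).sum() <= 1
            or total_w < 2 * self.min_leaf_weight
            or (self.max_depth is not None and depth >= self.max_depth)
        ):
            return self.leaf(idx, w)
        base = _entropy(class_w)
        candidates = self.split_candidates(idx, w, base, total_w)
        candidates = [c for c in candidates if c[1] > 1e-12]
        if not candidates:
            return self.leaf(idx, w)
        avg_gain = sum(c[1] for c in candidates) / len(candidates)
        eligible = [c for c in candidates if c[1] >= avg_gain - 1e-12]
        # best gain ratio; ties -> attribute order
        attr_pos = {a: i for i, a in enumerate(self.attrs)}
        attr, gain, ratio, (mode, thr) = max(
            eligible, key=lambda c: (c[2], -attr_pos[c[0]])
        )
        node = TreeNode(attribute=attr)
        if mode == "nominal":
            codes = self.columns[attr][idx]
            heaviest, heaviest_w = None, -1.0
            n_children = 0
            for code, value in enumerate(self.categories[attr]):
                sub = idx[codes == code]
                if len(sub) == 0:
                    continue
                sub_w = float(w[sub].sum())
                if sub_w < self.min_leaf_weight:
                    child = self.leaf(sub, w)
                else:
                    child = self.build(sub, w, depth + 1)
                node.children[value] = child
                n_children += 1
                if sub_w > heaviest_w:
                    heaviest, heaviest_w = value, sub_w
            if n_children < 2:
                return self.leaf(idx, w)
            node.default_key = heaviest
        else:
            node.threshold = thr
            vals = self.columns[attr][idx]
            known = ~np.isnan(vals)
            le_mask = known & (vals <= thr)
            gt_mask = known & (vals > thr)
            le_w = float(w[idx[le_mask]].sum())
            gt_w = float(w[idx[gt_mask]].sum())
            # missing rows go with the heavier side
            if (~known).any():
                if le_w >= gt_w:
                    le_mask = le_mask | ~known
                else:
                    gt_mask = gt_mask | ~known
            le_idx, gt_idx = idx[le_mask], idx[gt_mask]
            if len(le_idx) == 0 or len(gt_idx) == 0:
                return self.leaf(idx, w)
            for key, sub in (("le", le_idx), ("gt", gt_idx)):
                sub_w = float(w[sub].sum())
                if sub_w < self.min_leaf_weight:
                    node.children[key] = self.leaf(sub, w)
                else:
                    node.children[key] = self.build(sub, w, depth + 1)
            node.default_key = "le" if float(w[le_idx].sum()) >= float(w[gt_idx].sum()) else "gt"
        return node


def _route(node: TreeNode, row: dict) -> TreeNode:
    while not node.is_leaf:
        v = row.get(node.attribute)
        if node.threshold is None:
            key = "\0MISSING" if is_missing(v) else v
            child = node.children.get(key)
            if child is None:  # unseen category -> heaviest child
                child = node.children[node.default_key]
        else:
            if is_missing(v):
                child = node.children[node.default_key]
            else:
                child = node.children["le" if float(v) <= node.threshold else "gt"]
        node = child
    return node


class C45Tree(ClassifierMixin, BaseEstimator):
    """Weighted C4.5-style decision tree.

    Parameters
    ----------
    min_leaf_weight : float, default 2.0
        Minimum total instance weight per leaf, in units of whole
        instances (weights are rescaled so they sum to n before growing).
    max_depth : int or None
        Depth limit; None grows until purity.
    feature_kinds : mapping or None
        Attribute kind per column (``real``/``ordered`` threshold splits,
        ``nominal``/``binary`` multiway).  Unlisted numeric columns are
        treated as real, others nominal.
    """

    def __init__(self, min_leaf_weight=2.0, max_depth=None, feature_kinds=None):
        self.min_leaf_weight = min_leaf_weight
        self.max_depth = max_depth
        self.feature_kinds = feature_kinds

    def _kinds_for(self, X: pd.DataFrame) -> dict:
        kinds = dict(self.feature_kinds or {})
        for c in X.columns:
            if c not in kinds:
                kinds[c] = "real" if pd.api.types.is_numeric_dtype(X[c]) else "nominal"
        return kinds

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        X = pd.DataFrame(X)
        y = list(np.asarray(y, dtype=object))
        n = len(X)
        if sample_weight is None:
            w = np.ones(n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if (w < 0).any() or w.sum() <= 0:
                raise ValueError("sample weights must be non-negative and not all zero")
        # scale so weights are in whole-instance units (scale invariance)
        w = w * (n / w.sum())
        classes = sorted(set(y), key=lambda c: str(c))
        self.classes_ = np.array(classes, dtype=object)
        class_order = {c: i for i, c in enumerate(classes)}
        y_codes = np.array([class_order[label] for label in y], dtype=np.intp)
        global_counts = np.bincount(y_codes, weights=w, minlength=len(classes))

        kinds = self._kinds_for(X)
        columns: dict = {}
        categories: dict = {}
        for a in X.columns:
            col = X[a]
            if kinds.get(a, "real") in ("nominal", "binary"):
                cats: dict = {}
                codes = np.empty(n, dtype=np.intp)
                for i, v in enumerate(col):
                    key = "\0MISSING" if is_missing(v) else v
                    codes[i] = cats.setdefault(key, len(cats))
                columns[a] = codes
                categories[a] = list(cats)
            else:
                vals = np.array(
                    [np.nan if is_missing(v) else float(v) for v in col], dtype=float
                )
                columns[a] = vals
                categories[a] = None

        builder = _TreeBuilder(
            attrs=list(X.columns),
            kinds=kinds,
            columns=columns,
            categories=categories,
            y_codes=y_codes,
            classes=classes,
            min_leaf_weight=self.min_leaf_weight,
            max_depth=self.max_depth,
            global_counts=global_counts,
        )
        self.tree_ = builder.build(np.arange(n), w, depth=0)
        self.feature_names_in_ = np.array(list(X.columns), dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        rows = X.to_dict(orient="records")
        return np.array([_route(self.tree_, r).label for r in rows], dtype=object)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        rows = X.to_dict(orient="records")
        out = np.zeros((len(rows), len(self.classes_)))
        for i, r in enumerate(rows):
            leaf = _route(self.tree_, r)
            for j, c in enumerate(self.classes_):
                out[i, j] = leaf.proba.get(c, 0.0)
        return out


def train_tree(table: DecisionTable, instance_weights=None, **params) -> C45Tree:
    """Fit a :class:`C45Tree` on a decision table (functional wrapper)."""
    tree = C45Tree(feature_kinds=dict(table.kinds), **params)
    X = table.data[table.condition_attributes]
    return tree.fit(X, table.decision_values(), sample_weight=instance_weights)


class BoostedC45(ClassifierMixin, BaseEstimator):
    """AdaBoost.M1 ensemble of weighted C4.5-style trees (binary labels).

    Parameters
    ----------
    n_estimators : int, default 50
        Requested number of boosting rounds (the ensemble may hold fewer:
        rounds with weighted error >= 0.5 are discarded, and a zero-error
        round ends training because subsequent rounds would duplicate it).
    positive : label or None
        Label treated as the positive class by :meth:`decision_function`;
        default is the last of the sorted labels.
    resample : bool, default False
        Draw a weighted bootstrap sample each round instead of passing
        weights to the tree (needs ``random_state``).

    Attributes
    ----------
    estimators_ : list of (C45Tree, float)
        Fitted trees with their vote weights.
    n_effective_ : int
        Number of accepted rounds.
    round_errors_ : list of float
        Weighted training error of each accepted round (all < 0.5).
    round_weight_sums_ : list of float
        Instance-weight total after each accepted round's renormalization.
    """

    def __init__(self, n_estimators=50, min_leaf_weight=2.0, max_depth=None,
                 feature_kinds=None, positive=None, resample=False, random_state=0):
        self.n_estimators = n_estimators
        self.min_leaf_weight = min_leaf_weight
        self.max_depth = max_depth
        self.feature_kinds = feature_kinds
        self.positive = positive
        self.resample = resample
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        X = pd.DataFrame(X).reset_index(drop=True)
        y = np.asarray(list(y), dtype=object)
        classes = sorted(set(y.tolist()), key=lambda c: str(c))
        if len(classes) != 2:
            raise ValueError("boosting requires a binary decision attribute")
        self.classes_ = np.array(classes, dtype=object)
        self.positive_ = self.positive if self.positive is not None else classes[1]
        n = len(X)
        rng = np.random.default_rng(self.random_state)
        w = np.full(n, 1.0 / n)
        members: list[tuple[C45Tree, float]] = []
        n_effective = 0
        uniform = np.full(n, 1.0 / n)
        round_errors: list[float] = []
        round_weight_sums: list[float] = []
        for _round in range(self.n_estimators):
            was_uniform = np.allclose(w, uniform)
            if self.resample:
                idx = rng.choice(n, size=n, replace=True, p=w)
                tree = C45Tree(
                    min_leaf_weight=self.min_leaf_weight,
                    max_depth=self.max_depth,
                    feature_kinds=self.feature_kinds,
                ).fit(X.iloc[idx], y[idx])
            else:
                tree = C45Tree(
                    min_leaf_weight=self.min_leaf_weight,
                    max_depth=self.max_depth,
                    feature_kinds=self.feature_kinds,
                ).fit(X, y, sample_weight=w)
            pred = tree.predict(X)
            wrong = pred != y
            eps = float(w[wrong].sum())
            if eps <= 0.0:
                members.append((tree, ALPHA_CAP))
                n_effective += 1
                round_errors.append(eps)
                w = uniform.copy()
                round_weight_sums.append(float(w.sum()))
                if was_uniform:
                    # the reset state would regrow the identical tree forever
                    break
                continue
            if eps >= 0.5:
                log.info("boost: round %d discarded (weighted error %.3f >= 0.5)", _round, eps)
                w = uniform.copy()
                if was_uniform and not self.resample:
                    # deterministic dead end: every further round is identical
                    break
                continue
            alpha = 0.5 * math.log((1.0 - eps) / eps)
            members.append((tree, alpha))
            n_effective += 1
            round_errors.append(eps)
            w = w * np.exp(np.where(wrong, alpha, -alpha))
            w = w / w.sum()
            round_weight_sums.append(float(w.sum()))
        if not members:
            warnings.warn(
                "all boosting rounds discarded; falling back to the single "
                "uniform-weight tree",
                UserWarning,
                stacklevel=2,
            )
            tree = C45Tree(
                min_leaf_weight=self.min_leaf_weight,
                max_depth=self.max_depth,
                feature_kinds=self.feature_kinds,
            ).fit(X, y)
            members.append((tree, 1.0))
            n_effective = 1
        self.estimators_ = members
        self.n_requested_ = self.n_estimators
        self.n_effective_ = n_effective
        self.round_errors_ = round_errors
        self.round_weight_sums_ = round_weight_sums
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Normalized weighted vote in [-1, 1]; positive sign = positive class."""
        X = pd.DataFrame(X)
        total = sum(alpha for _, alpha in self.estimators_)
        score = np.zeros(len(X))
        for tree, alpha in self.estimators_:
            vote = np.where(tree.predict(X) == self.positive_, 1.0, -1.0)
            score += alpha * vote
        return score / total if total > 0 else score

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        score = self.decision_function(X)
        negative = [c for c in self.classes_ if c != self.positive_][0]
        # ties (score exactly 0) go to the positive class
        return np.where(score >= 0, self.positive_, negative)


def boost(table: DecisionTable, k: int, seed: int = 0, **params) -> BoostedC45:
    """Fit an AdaBoost.M1 ensemble on a decision table."""
    if k < 1:
        raise ValueError("k must be >= 1")
    positive = params.pop("positive", None)
    model = BoostedC45(
        n_estimators=k,
        feature_kinds=dict(table.kinds),
        positive=positive,
        random_state=seed,
        **params,
    )
    X = table.data[table.condition_attributes]
    return model.fit(X, table.decision_values())


def predict_score(model: BoostedC45, instance) -> float:
    """Ensemble score for one instance (mapping or Series), in [-1, 1]."""
    if not model.estimators_:
        raise ValueError("model has no members")
    row = pd.DataFrame([dict(instance)])
    return float(model.decision_function(row)[0])
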