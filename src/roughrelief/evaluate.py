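"""Confusion-matrix metrics, split protocols, and ROC analysis.

Sensitivity, specificity and accuracy follow the usual clinical
definitions (Sn = TP/(TP+FN), Sp = TN/(FP+TN), Acc = (TP+TN)/total), with
the *presence* of disease as the positive class.  Metrics with an empty
denominator are reported as NaN, never silently as zero.  Validation
protocols: stratified 70/30 splits and leave-one-out (jackknife)
cross-validation.  ROC curves are computed by a descending threshold
sweep with tied scores grouped into single steps; AUC by the trapezoid
rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .table import DecisionTable

__all__ = [
    "ConfusionMatrix",
    "MetricReport",
    "ROCCurve",
    "confusion",
    "metrics",
    "split_70_30",
    "jackknife",
    "roc",
]


@dataclass
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp, self.tn + other.tn
        )


@dataclass
class MetricReport:
    """Sensitivity / specificity / accuracy as fractions in [0, 1].

    Undefined metrics (empty denominator) are NaN.  ``*_pct`` properties
    give the percentage scale used in reports; rounding happens only at
    presentation time.
    """

    sensitivity: float
    specificity: float
    accuracy: float

    @property
    def sensitivity_pct(self) -> float:
        return self.sensitivity * 100.0

    @property
    def specificity_pct(self) -> float:
        return self.specificity * 100.0

    @property
    def accuracy_pct(self) -> float:
        return self.accuracy * 100.0

    def as_percent_dict(self, ndigits: int = 2) -> dict:
        def fmt(x):
            return float("nan") if math.isnan(x) else round(x * 100.0, ndigits)

        return {
            "Sn": fmt(self.sensitivity),
            "Sp": fmt(self.specificity),
            "Acc": fmt(self.accuracy),
        }


@dataclass
class ROCCurve:
    points: list[tuple[float, float]]  # (FPR, TPR), threshold descending
    auc: float


def confusion(actual, predicted, positive) -> ConfusionMatrix:
    """Count TP/FN/FP/TN with *positive* as the disease class."""
    actual = list(actual)
    predicted = list(predicted)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    if not actual:
        raise ValueError("need at least one labelled instance")
    tp = fn = fp = tn = 0
    for a, p in zip(actual, predicted):
        if a == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fn=fn, fp=fp, tn=tn)


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Sn, Sp, Acc from a confusion matrix; NaN where undefined."""
    sn = cm.tp / cm.positives if cm.positives > 0 else float("nan")
    sp = cm.tn / cm.negatives if cm.negatives > 0 else float("nan")
    acc = (cm.tp + cm.tn) / cm.total if cm.total > 0 else float("nan")
    return MetricReport(sensitivity=sn, specificity=sp, accuracy=acc)


def split_70_30(
    table: DecisionTable, seed: int = 0, stratified: bool = True
) -> tuple[DecisionTable, DecisionTable]:
    """Disjoint, exhaustive 70/30 train/test split.

    Test size is ``round(0.3 * |U|)``.  Stratified mode allocates the test
    quota per class by largest remainder, keeping test class proportions
    within one object of the global ones.
    """
    n = table.n_objects
    n_test = int(round(0.3 * n))
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    if stratified:
        y = table.decision_values()
        classes, y_codes = np.unique(y, return_inverse=True)
        counts = np.bincount(y_codes, minlength=len(classes))
        if (counts < 2).any():
            raise ValueError("stratified split needs >= 2 objects per class")
        exact = counts * n_test / n
        quota = np.floor(exact).astype(int)
        remainder = exact - quota
        short = n_test - quota.sum()
        for c in np.argsort(-remainder, kind="stable")[:short]:
            quota[c] += 1
        test_parts = []
        for c in range(len(classes)):
            members = idx[y_codes == c]
            test_parts.append(rng.permutation(members)[: quota[c]])
        test_idx = np.sort(np.concatenate(test_parts))
    else:
        perm = rng.permutation(idx)
        test_idx = np.sort(perm[:n_test])
    test_mask = np.zeros(n, dtype=bool)
    test_mask[test_idx] = True
    objs = np.array(table.objects, dtype=object)
    train = table.subset_rows(objs[~test_mask].tolist())
    test = table.subset_rows(objs[test_mask].tolist())
    return train, test


def jackknife(table: DecisionTable, trainer, positive) -> tuple[ConfusionMatrix, MetricReport]:
    """Leave-one-out validation.

    *trainer* is called with the table minus one object and must return a
    ``predict(row: pandas.Series) -> label`` callable; the held-out object
    is then predicted and the confusion matrix aggregated over all |U|
    folds.  A trainer failure aborts the run, naming the fold.
    """
    if table.n_objects < 2:
        raise ValueError("jackknife needs at least 2 objects")
    objs = table.objects
    actual = []
    predicted = []
    for i, obj in enumerate(objs):
        rest = [o for o in objs if o != obj]
        train = table.subset_rows(rest)
        try:
            predict = trainer(train)
            row = table.data.loc[obj, table.condition_attributes]
            pred = predict(row)
        except Exception as exc:  # noqa: BLE001 - surfaced with fold context
            raise RuntimeError(f"jackknife fold {i} (object {obj!r}) failed: {exc}") from exc
        actual.append(table.data.loc[obj, table.decision])
        predicted.append(pred)
    cm = confusion(actual, predicted, positive)
    return cm, metrics(cm)


def roc(scores, actual, positive) -> ROCCurve:
    """ROC curve and trapezoid AUC from continuous scores.

    Thresholds sweep the distinct score values in descending order; tied
    scores move as one step.  The curve starts at (0, 0) and ends at
    (1, 1).
    """
    scores = np.asarray(list(scores), dtype=float)
    actual = np.asarray(list(actual), dtype=object)
    pos_mask = actual == positive
    P = int(pos_mask.sum())
    N = int(len(actual) - P)
    if P == 0 or N == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if pos_mask[order[j]]:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / N, tp / P))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return ROCCurve(points=points, auc=auc)
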