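"""ReliefF feature weighting with probabilistic missing-value handling.

ReliefF scores each condition attribute by how well it separates an
instance from its *nearest misses* (closest instances of other classes)
relative to its *nearest hits* (closest instances of the same class).
Attributes that differ between classes but agree within a class receive
positive weight; class-independent attributes drift toward zero.

The per-attribute dissimilarity ``diff`` is 0/1 for categorical attributes
and a range-normalized absolute difference for real ones.  When a value is
unobserved, ``diff`` falls back to class-conditional value frequencies:
with one side missing it is ``1 - P(observed value | class of the missing
instance)``; with both sides missing it is ``1 - sum_v P(v | class_1) *
P(v | class_2)``.  Conditional probabilities are relative frequencies over
the non-missing values in the table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .table import DecisionTable

__all__ = [
    "WeightVector",
    "diff",
    "relieff_weights",
    "select_features",
    "ReliefFWeighter",
    "ReliefFSelector",
]

log = logging.getLogger(__name__)


@dataclass
class WeightVector:
    """Per-attribute ReliefF weights plus the parameters that produced them."""

    weights: dict[str, float]
    k_neighbors: int
    n_samples: int | None  # None = every instance used as anchor
    threshold: float | None = None
    seed: int | None = None

    def ranking(self) -> list[str]:
        """Attributes sorted by decreasing weight (ties: table order)."""
        names = list(self.weights)
        return sorted(names, key=lambda a: (-self.weights[a], names.index(a)))

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, dtype=float)


# ---------------------------------------------------------------------------
# diff
# ---------------------------------------------------------------------------

class _DiffEngine:
    """Precomputed per-attribute structures for fast pairwise diffs."""

    def __init__(self, table: DecisionTable):
        self.table = table
        self.attrs = table.condition_attributes
        y = table.decision_values()
        self.classes, self.y_codes = np.unique(y, return_inverse=True)
        self.n = table.n_objects
        counts = np.bincount(self.y_codes, minlength=len(self.classes))
        self.priors = counts / self.n
        self._cols: dict[str, dict] = {}
        for a in self.attrs:
            self._cols[a] = self._prepare(a)

    def _prepare(self, a: str) -> dict:
        kind = self.table.kinds[a]
        raw = self.table.data[a]
        miss = raw.isna().to_numpy()
        info: dict = {"kind": kind, "miss": miss}
        if kind == "real":
            vals = raw.astype(float).to_numpy()
            known = vals[~miss]
            rng = float(known.max() - known.min()) if len(known) else 0.0
            info["vals"] = vals
            info["range"] = rng
        else:
            info["vals"] = raw.to_numpy()
        # class-conditional relative frequencies over the observed values,
        # used only when a comparison involves a missing cell
        known_vals = info["vals"][~miss]
        uniq = pd.unique(known_vals)
        code_of = {v: i for i, v in enumerate(uniq)}
        codes = np.full(self.n, -1, dtype=int)
        for i in range(self.n):
            if not miss[i]:
                codes[i] = code_of[info["vals"][i]]
        freq = np.zeros((len(self.classes), max(len(uniq), 1)))
        for c in range(len(self.classes)):
            sel = (self.y_codes == c) & ~miss
            if sel.sum():
                freq[c] = np.bincount(codes[sel], minlength=max(len(uniq), 1)) / sel.sum()
            else:
                # no observed value in this class: fall back to the global
                # relative frequencies
                if (~miss).sum():
                    freq[c] = np.bincount(codes[~miss], minlength=max(len(uniq), 1)) / (~miss).sum()
        info["codes"] = codes
        info["freq"] = freq
        # Sum_v P(v|c1) P(v|c2), for the both-missing case
        info["freq_dot"] = freq @ freq.T
        return info

    def pair(self, a: str, i: int, j: int) -> float:
        info = self._cols[a]
        mi, mj = info["miss"][i], info["miss"][j]
        if not mi and not mj:
            if info["kind"] == "real":
                if info["range"] == 0.0:
                    return 0.0
                return abs(info["vals"][i] - info["vals"][j]) / info["range"]
            return 0.0 if info["vals"][i] == info["vals"][j] else 1.0
        ci, cj = self.y_codes[i], self.y_codes[j]
        if mi and mj:
            return 1.0 - float(info["freq_dot"][ci, cj])
        if mi:  # value of j is known; condition on the class of i
            return 1.0 - float(info["freq"][ci, info["codes"][j]])
        return 1.0 - float(info["freq"][cj, info["codes"][i]])

    def matrix(self, a: str) -> np.ndarray:
        """Full n x n diff matrix for attribute *a* (diagonal zeroed)."""
        info = self._cols[a]
        miss = info["miss"]
        n = self.n
        if info["kind"] == "real":
            v = np.where(miss, 0.0, np.nan_to_num(info["vals"].astype(float), nan=0.0))
            if info["range"] == 0.0:
                D = np.zeros((n, n))
            else:
                D = np.abs(v[:, None] - v[None, :]) / info["range"]
        else:
            codes = info["codes"]
            D = (codes[:, None] != codes[None, :]).astype(float)
        if miss.any():
            idx = np.flatnonzero(miss)
            known = np.flatnonzero(~miss)
            freq = info["freq"]
            for i in idx:
                ci = self.y_codes[i]
                if len(known):
                    row = 1.0 - freq[ci, info["codes"][known]]
                    D[i, known] = row
                    D[known, i] = row
            # both missing
            for i in idx:
                D[i, idx] = 1.0 - info["freq_dot"][self.y_codes[i], self.y_codes[idx]]
        np.fill_diagonal(D, 0.0)
        return np.clip(D, 0.0, 1.0)


def diff(attribute: str, inst1, inst2, table: DecisionTable) -> float:
    """Per-attribute dissimilarity of two instances, in [0, 1].

    ``inst1``/``inst2`` are object identifiers (index labels of the table).
    """
    if attribute not in table.condition_attributes:
        raise KeyError(f"{attribute!r} is not a condition attribute")
    engine = _DiffEngine(table)
    pos = {obj: i for i, obj in enumerate(table.objects)}
    return engine.pair(attribute, pos[inst1], pos[inst2])


# ---------------------------------------------------------------------------
# ReliefF weights
# ---------------------------------------------------------------------------

def relieff_weights(
    table: DecisionTable,
    k_neighbors: int = 10,
    n_samples: int | None = None,
    seed: int | None = None,
    normalize: bool = True,
) -> WeightVector:
    """Estimate attribute weights with the multi-class ReliefF update.

    Every anchor contributes minus the average diff to its ``k`` nearest
    same-class hits and, for each other class ``c``, plus the prior-weighted
    ``P(c) / (1 - P(class(anchor)))`` average diff to its ``k`` nearest
    misses in ``c``; contributions are averaged over anchors.  Neighbors are
    nearest by the Manhattan sum of per-attribute diffs; instances tied at
    the k-th distance contribute fractionally (their group average fills
    the remaining slots), which makes the weights deterministic and exactly
    invariant under object reordering.

    ``n_samples=None`` uses every instance as an anchor (deterministic);
    an integer requests that many anchors sampled without replacement with
    *seed*.  ``normalize`` keeps the conventional range scaling of real
    attributes inside ``diff``; switching it off compares raw absolute
    differences (sensitivity analyses only).
    """
    y = table.decision_values()
    classes, y_codes = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("weights undefined for one class")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")

    engine = _DiffEngine(table)
    attrs = table.condition_attributes
    n = table.n_objects
    mats = {a: engine.matrix(a) for a in attrs}
    if not normalize:
        for a in attrs:
            info = engine._cols[a]
            if info["kind"] == "real" and info["range"] not in (0.0,):
                mats[a] = mats[a] * info["range"]
    D = sum(mats.values())

    if n_samples is None or n_samples >= n:
        anchors = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        anchors = np.sort(rng.choice(n, size=n_samples, replace=False))
    m = len(anchors)

    class_members = {c: np.flatnonzero(y_codes == c) for c in range(len(classes))}
    priors = np.bincount(y_codes, minlength=len(classes)) / n

    W = {a: 0.0 for a in attrs}
    truncated = False
    for i in anchors:
        ci = y_codes[i]
        drow = D[i]
        for c, members in class_members.items():
            cand = members[members != i]
            if len(cand) == 0:
                continue
            k = min(k_neighbors, len(cand))
            if k < k_neighbors:
                truncated = True
            # k nearest with fractional averaging over the tied boundary
            # group, so the result is invariant under object reordering
            d = drow[cand]
            thr = np.partition(d, k - 1)[k - 1]
            closer = d < thr
            tied = d == thr
            frac = (k - closer.sum()) / tied.sum()
            nbr_w = closer + tied * frac
            if c == ci:
                for a in attrs:
                    W[a] -= float(mats[a][i, cand] @ nbr_w) / (k * m)
            else:
                factor = priors[c] / (1.0 - priors[ci])
                for a in attrs:
                    W[a] += factor * float(mats[a][i, cand] @ nbr_w) / (k * m)
    if truncated:
        log.info("relieff_weights: some classes had fewer than k=%d neighbors; k truncated", k_neighbors)
    return WeightVector(
        weights={a: float(W[a]) for a in attrs},
        k_neighbors=k_neighbors,
        n_samples=None if n_samples is None or n_samples >= n else n_samples,
        seed=seed,
    )


def select_features(wv: WeightVector, delta: float) -> list[str]:
    """Attributes whose weight strictly exceeds *delta* (table order)."""
    selected = [a for a, w in wv.weights.items() if w > delta]
    if not selected:
        warnings.warn(
            f"no attribute weight exceeds delta={delta}; empty selection",
            UserWarning,
            stacklevel=2,
        )
    return selected


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class ReliefFWeighter(BaseEstimator):
    """Estimator wrapper around :func:`relieff_weights`.

    Attributes
    ----------
    weights_ : pandas.Series
        Weight per condition attribute, in table order.
    ranking_ : list of str
        Attributes by decreasing weight.
    """

    def __init__(self, k_neighbors=10, n_samples=None, normalize=True, random_state=None):
        self.k_neighbors = k_neighbors
        self.n_samples = n_samples
        self.normalize = normalize
        self.random_state = random_state

    def fit(self, table: DecisionTable, y=None):
        wv = relieff_weights(
            table,
            k_neighbors=self.k_neighbors,
            n_samples=self.n_samples,
            seed=self.random_state,
            normalize=self.normalize,
        )
        self.weight_vector_ = wv
        self.weights_ = wv.as_series()
        self.ranking_ = wv.ranking()
        return self


class ReliefFSelector(TransformerMixin, ReliefFWeighter):
    """ReliefF weighting plus threshold selection as a table transformer.

    ``transform`` projects the table onto the attributes whose weight
    strictly exceeds ``delta``.
    """

    def __init__(self, k_neighbors=10, delta=0.02, n_samples=None, normalize=True,
                 random_state=None):
        super().__init__(k_neighbors=k_neighbors, n_samples=n_samples,
                         normalize=normalize, random_state=random_state)
        self.delta = delta

    def fit(self, table: DecisionTable, y=None):
        super().fit(table)
        self.selected_ = select_features(self.weight_vector_, self.delta)
        self.weight_vector_.threshold = self.delta
        return self

    def transform(self, table: DecisionTable) -> DecisionTable:
        if not self.selected_:
            raise ValueError("empty feature selection; lower delta")
        return table.project(self.selected_)
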