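"""Equal-interval discretization of continuous condition attributes.

Rough-set reduction operates on categorical data, so continuous attributes
are binned first.  Cut points divide the observed [min, max] range of each
real attribute into ``n_bins`` equal-width intervals; assignment is
right-closed (a value equal to a cut falls in the lower bin) and values
outside the fitted range are clipped into the first or last bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from sklearn.base import BaseEstimator, TransformerMixin

from .table import DecisionTable, MISSING, is_missing

__all__ = ["BinningSpec", "EqualIntervalDiscretizer", "fit_equal_interval", "apply_binning"]

log = logging.getLogger(__name__)


@dataclass
class BinningSpec:
    """Fitted cut points per attribute.

    ``cut_points[a]`` is a strictly increasing list of bin edges; the number
    of bins is ``len(cut_points[a]) + 1``.  A constant attribute gets an
    empty cut list (single bin).
    """

    cut_points: dict[str, list[float]] = field(default_factory=dict)
    fitted_range: dict[str, tuple[float, float]] = field(default_factory=dict)

    def n_bins(self, attribute: str) -> int:
        return len(self.cut_points[attribute]) + 1

    @property
    def attributes(self) -> list[str]:
        return list(self.cut_points)


def fit_equal_interval(
    table: DecisionTable, n_bins: int, attributes=None
) -> BinningSpec:
    """Fit equal-width cut points on the observed range of real attributes.

    For an attribute with observed min ``m`` and max ``M`` the cuts sit at
    ``m + i*(M-m)/n_bins`` for ``i = 1..n_bins-1``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if attributes is None:
        attributes = [a for a in table.condition_attributes if table.kinds[a] == "real"]
    spec = BinningSpec()
    for a in attributes:
        if table.kinds[a] != "real":
            raise ValueError(f"attribute {a!r} is {table.kinds[a]}, not real")
        col = table.data[a].astype(float)
        known = col[col.notna()]
        if len(known) == 0:
            raise ValueError(f"attribute {a!r} has no observed values")
        m, M = float(known.min()), float(known.max())
        spec.fitted_range[a] = (m, M)
        if m == M:
            spec.cut_points[a] = []  # constant attribute: one bin, no error
            continue
        width = (M - m) / n_bins
        spec.cut_points[a] = [m + i * width for i in range(1, n_bins)]
    return spec


def _assign_bin(value: float, cuts: list[float]) -> int:
    # right-closed: v <= cut_i -> bin i; beyond the last cut -> last bin
    for i, c in enumerate(cuts):
        if value <= c:
            return i
    return len(cuts)


def apply_binning(table: DecisionTable, spec: BinningSpec) -> DecisionTable:
    """Replace fitted attributes by their bin codes (ordered kind).

    Missing values stay missing; attributes absent from the spec are left
    untouched.  Out-of-range values are clipped into the boundary bins and
    logged.
    """
    out = table.copy()
    for a in spec.attributes:
        if a not in table.condition_attributes:
            raise KeyError(f"spec attribute {a!r} not in table")
        if table.kinds[a] != "real":
            # already categorical (e.g. refit on a binned table): idempotent
            continue
        cuts = spec.cut_points[a]
        lo, hi = spec.fitted_range.get(a, (-np.inf, np.inf))
        codes = []
        clipped = 0
        for v in table.data[a]:
            if is_missing(v):
                codes.append(MISSING)
                continue
            v = float(v)
            if v < lo or v > hi:
                clipped += 1
            codes.append(_assign_bin(v, cuts))
        if clipped:
            log.info("apply_binning: %d values of %s clipped to boundary bins", clipped, a)
        out.data[a] = np.array(codes, dtype=object)
        out.kinds[a] = "ordered"
        out.domains[a] = list(range(len(cuts) + 1))
    return out


class EqualIntervalDiscretizer(TransformerMixin, BaseEstimator):
    """Equal-width binning transformer for decision tables.

    Parameters
    ----------
    n_bins : int, default 4
        Number of equal-width intervals per real attribute.
    attributes : list of str or None
        Attributes to bin; default all real-kind condition attributes of
        the table seen at fit time.

    Attributes
    ----------
    spec_ : BinningSpec
        Fitted cut points.
    """

    def __init__(self, n_bins: int = 4, attributes=None):
        self.n_bins = n_bins
        self.attributes = attributes

    def fit(self, table: DecisionTable, y=None):
        self.spec_ = fit_equal_interval(table, self.n_bins, self.attributes)
        return self

    def transform(self, table: DecisionTable) -> DecisionTable:
        return apply_binning(table, self.spec_)
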