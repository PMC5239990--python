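"""Decision tables: the information system S = (U, A = C ∪ D, V, F).

A :class:`DecisionTable` holds a finite universe of objects described by a
set of *condition* attributes plus a single *decision* attribute, together
with per-attribute value domains and kind tags (``real``, ``nominal``,
``ordered``, ``binary``).  Missing condition values are represented by a
dedicated sentinel (:data:`MISSING`, an alias of :data:`pandas.NA`), never
by a numeric code; the decision attribute must be fully observed.

Readers are provided for the UCI Statlog (Heart) flat-file layout (13
attribute columns plus a 1/2 class column) and for generic headered CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "is_missing",
    "Kind",
    "DecisionTable",
    "ParseError",
    "ValidationError",
    "STATLOG_KINDS",
    "STATLOG_DOMAINS",
    "read_statlog",
    "read_csv_table",
    "write_csv",
    "summarize",
]

#: Sentinel for an unobserved condition-attribute value.
MISSING = pd.NA

KINDS = ("real", "nominal", "ordered", "binary")
Kind = str


def is_missing(value) -> bool:
    """True iff *value* is the missing sentinel (or any NA-like scalar)."""
    try:
        return bool(pd.isna(value))
    except (TypeError, ValueError):
        return False


class ParseError(ValueError):
    """Raised when an input file cannot be parsed into a decision table."""


class ValidationError(ValueError):
    """Raised when parsed data violates a decision-table invariant."""


@dataclass
class DecisionTable:
    """An information system with one decision attribute.

    Parameters
    ----------
    data
        One row per object.  Columns are the condition attributes plus the
        decision column; real-kind columns are float, all others object
        dtype.  Missing condition cells hold :data:`MISSING`.
    decision
        Name of the decision column.
    kinds
        Kind tag per condition attribute.
    domains
        Value domain per condition attribute: ``(min, max)`` for real
        attributes, a sorted list of admissible values otherwise.
    """

    data: pd.DataFrame
    decision: str
    kinds: dict[str, Kind]
    domains: dict[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.decision not in self.data.columns:
            raise ValidationError(f"decision column {self.decision!r} not in data")
        if len(self.data) < 1:
            raise ValidationError("a decision table needs at least one object")
        if self.data.columns.duplicated().any():
            raise ValidationError("attribute names must be unique")
        for a in self.condition_attributes:
            if a not in self.kinds:
                raise ValidationError(f"no kind declared for attribute {a!r}")
            if self.kinds[a] not in KINDS:
                raise ValidationError(f"unknown kind {self.kinds[a]!r} for {a!r}")
        if self.data[self.decision].isna().any():
            raise ValidationError("decision attribute has missing values")
        if not self.domains:
            self.domains = _infer_domains(self.data, self.kinds)

    # -- basic accessors ---------------------------------------------------
    @property
    def objects(self) -> list:
        return list(self.data.index)

    @property
    def n_objects(self) -> int:
        return len(self.data)

    @property
    def condition_attributes(self) -> list[str]:
        return [c for c in self.data.columns if c != self.decision]

    @property
    def classes(self) -> list:
        return sorted(pd.unique(self.data[self.decision]).tolist())

    def decision_values(self) -> np.ndarray:
        return self.data[self.decision].to_numpy()

    def column(self, attribute: str) -> np.ndarray:
        return self.data[attribute].to_numpy()

    # -- derived tables ----------------------------------------------------
    def project(self, attributes: Iterable[str]) -> "DecisionTable":
        """Restrict to a subset of condition attributes (decision kept)."""
        attrs = [a for a in self.condition_attributes if a in set(attributes)]
        missing = set(attributes) - set(attrs)
        if missing:
            raise KeyError(f"unknown condition attributes: {sorted(missing)}")
        return DecisionTable(
            data=self.data[attrs + [self.decision]].copy(),
            decision=self.decision,
            kinds={a: self.kinds[a] for a in attrs},
            domains={a: self.domains[a] for a in attrs},
        )

    def subset_rows(self, index) -> "DecisionTable":
        """Table restricted to the given object index (domains preserved)."""
        return DecisionTable(
            data=self.data.loc[index].copy(),
            decision=self.decision,
            kinds=dict(self.kinds),
            domains=dict(self.domains),
        )

    def copy(self) -> "DecisionTable":
        return DecisionTable(self.data.copy(), self.decision, dict(self.kinds), dict(self.domains))

    def validate(self) -> None:
        """Check the value-domain invariant; raises ValidationError."""
        for a in self.condition_attributes:
            col = self.data[a]
            known = col[col.notna()]
            if self.kinds[a] == "real":
                lo, hi = self.domains[a]
                vals = known.astype(float)
                if len(vals) and (vals.min() < lo or vals.max() > hi):
                    raise ValidationError(f"{a}: value outside declared range [{lo}, {hi}]")
            else:
                dom = set(self.domains[a])
                bad = set(known.unique()) - dom
                if bad:
                    raise ValidationError(f"{a}: values {sorted(map(str, bad))} outside domain")

    def equals(self, other: "DecisionTable") -> bool:
        if self.decision != other.decision or self.kinds != other.kinds:
            return False
        if list(self.data.columns) != list(other.data.columns):
            return False
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if a.shape != b.shape:
            return False
        for c in a.columns:
            va, vb = a[c], b[c]
            if not ((va.isna() == vb.isna()).all() and (va.dropna() == vb.dropna()).all()):
                return False
        return True


def _infer_domains(data: pd.DataFrame, kinds: Mapping[str, Kind]) -> dict:
    domains: dict[str, object] = {}
    for a, kind in kinds.items():
        known = data[a][data[a].notna()]
        if kind == "real":
            vals = known.astype(float)
            domains[a] = (float(vals.min()), float(vals.max())) if len(vals) else (0.0, 0.0)
        else:
            domains[a] = sorted(known.unique().tolist())
    return domains


# ---------------------------------------------------------------------------
# Statlog (Heart) flat file
# ---------------------------------------------------------------------------

#: Attribute kinds of the 13-feature Statlog (Heart) schema.  The vessel
#: count (C12) takes the 4 discrete values 0..3 and is kept ordered-discrete
#: rather than interval-binned.
STATLOG_KINDS: dict[str, Kind] = {
    "C1": "real",      # age
    "C2": "binary",    # sex
    "C3": "nominal",   # chest pain type
    "C4": "real",      # resting blood pressure
    "C5": "real",      # serum cholesterol
    "C6": "binary",    # fasting blood sugar > 120
    "C7": "nominal",   # resting ECG
    "C8": "real",      # max heart rate
    "C9": "binary",    # exercise-induced angina
    "C10": "real",     # ST depression (oldpeak)
    "C11": "ordered",  # ST slope
    "C12": "ordered",  # vessels colored by fluoroscopy
    "C13": "nominal",  # thallium scan
}

STATLOG_DOMAINS: dict[str, object] = {
    "C2": [0, 1],
    "C3": [1, 2, 3, 4],
    "C6": [0, 1],
    "C7": [0, 1, 2],
    "C9": [0, 1],
    "C11": [1, 2, 3],
    "C12": [0, 1, 2, 3],
    "C13": [3, 6, 7],
}

STATLOG_CLASS_MAP = {1: "absence", 2: "presence"}
STATLOG_COLUMNS = [f"C{i}" for i in range(1, 14)]


def _coerce_statlog_value(attr: str, raw: float):
    if STATLOG_KINDS[attr] == "real":
        return float(raw)
    iv = int(round(raw))
    if abs(raw - iv) > 1e-9:
        raise ValueError(f"non-integral value {raw} for categorical attribute {attr}")
    return iv


def read_statlog(path) -> DecisionTable:
    """Read a Statlog (Heart)-layout flat file into a decision table.

    Each row carries 13 whitespace- or comma-delimited attribute values
    followed by the class label (1 = absence, 2 = presence of disease).
    """
    text = Path(path).read_text()
    rows = []
    lines = [ln for ln in text.splitlines()]
    n_data = 0
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        fields = stripped.replace(",", " ").split()
        if len(fields) != 14:
            raise ParseError(f"line {lineno}: expected 14 fields, found {len(fields)}")
        try:
            values = [float(f) for f in fields]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        label = int(round(values[13]))
        if label not in STATLOG_CLASS_MAP or abs(values[13] - label) > 1e-9:
            raise ValidationError(f"line {lineno}: unknown class label {fields[13]!r}")
        try:
            record = {
                a: _coerce_statlog_value(a, v) for a, v in zip(STATLOG_COLUMNS, values[:13])
            }
        except ValueError as exc:
            raise ParseError(f"line {lineno}: {exc}") from exc
        record["class"] = STATLOG_CLASS_MAP[label]
        rows.append(record)
        n_data += 1
    if n_data == 0:
        raise ParseError("empty file: no data rows")
    data = pd.DataFrame(rows)
    for a, kind in STATLOG_KINDS.items():
        data[a] = data[a].astype(float) if kind == "real" else data[a].astype(object)
    domains = dict(STATLOG_DOMAINS)
    for a, kind in STATLOG_KINDS.items():
        if kind == "real":
            vals = data[a].astype(float)
            domains[a] = (float(vals.min()), float(vals.max()))
    return DecisionTable(data=data, decision="class", kinds=dict(STATLOG_KINDS), domains=domains)


# ---------------------------------------------------------------------------
# Generic CSV
# ---------------------------------------------------------------------------

def _parse_cell(raw: str, kind: Kind):
    if kind == "real":
        return float(raw)
    try:
        f = float(raw)
        if f == int(f):
            return int(f)
        return f
    except ValueError:
        return raw


def read_csv_table(
    path,
    decision_column: str,
    kinds: Mapping[str, Kind] | None = None,
    missing_token: str = "?",
) -> DecisionTable:
    """Read a headered CSV into a decision table.

    Cells equal to *missing_token* become :data:`MISSING`.  Column kinds not
    supplied in *kinds* are inferred: fully numeric columns with more than 8
    distinct values are ``real``, numeric columns with exactly the values
    {0,1} are ``binary``, everything else ``nominal``.  Domains are the
    observed values (min–max for reals).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if decision_column not in raw.columns:
        raise ParseError(f"decision column {decision_column!r} not found in header")
    kinds = dict(kinds or {})
    cond = [c for c in raw.columns if c != decision_column]
    if (raw[decision_column] == missing_token).any():
        raise ValidationError("decision column contains missing values")
    parsed = {}
    for c in cond:
        col = raw[c]
        known = col[col != missing_token]
        if c not in kinds:
            kinds[c] = _infer_kind(known)
        if kinds[c] == "real":
            cells = [np.nan if cell == missing_token else float(cell) for cell in col]
            parsed[c] = pd.Series(cells, dtype=float)
        else:
            cells = [MISSING if cell == missing_token else _parse_cell(cell, kinds[c]) for cell in col]
            parsed[c] = pd.Series(cells, dtype=object)
    parsed[decision_column] = pd.Series(
        [_parse_cell(v, "nominal") for v in raw[decision_column]], dtype=object
    )
    data = pd.DataFrame(parsed)[list(raw.columns)]
    return DecisionTable(data=data, decision=decision_column, kinds=kinds)


def _infer_kind(known: pd.Series) -> Kind:
    try:
        vals = known.astype(float)
    except ValueError:
        return "nominal"
    uniq = set(vals.unique().tolist())
    if uniq <= {0.0, 1.0}:
        return "binary"
    if len(uniq) > 8:
        return "real"
    return "nominal"


def write_csv(table: DecisionTable, path, missing_token: str = "?") -> None:
    """Canonical CSV writer; missing cells are written as *missing_token*."""
    out = table.data.copy()
    for a in table.condition_attributes:
        col = out[a]
        out[a] = col.map(lambda v: missing_token if is_missing(v) else _format_value(v))
    out[table.decision] = out[table.decision].map(_format_value)
    out.to_csv(path, index=False)


def _format_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def summarize(table: DecisionTable) -> dict[str, dict]:
    """Per-attribute summary over non-missing values.

    Real attributes report ``mean`` and (sample) ``std``; all other kinds
    report category ``counts``.  Never raises on a valid table.
    """
    out: dict[str, dict] = {}
    for a in table.condition_attributes:
        col = table.data[a]
        known = col[col.notna()]
        if table.kinds[a] == "real":
            vals = known.astype(float)
            mean = float(vals.mean()) if len(vals) else float("nan")
            std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            out[a] = {"kind": "real", "n": int(len(vals)), "mean": mean, "std": std}
        else:
            counts = known.value_counts().to_dict()
            out[a] = {"kind": table.kinds[a], "n": int(len(known)),
                      "counts": {k: int(v) for k, v in counts.items()}}
    return out
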