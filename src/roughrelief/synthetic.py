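"""Synthetic decision tables with planted structure.

``make_table`` builds categorical tables whose minimal reducts are known
by construction: *relevant* attributes jointly determine the class,
*redundant* attributes are value-permuted copies of relevant ones (hence
partition-identical), and *noise* attributes are class-independent.  With
no label noise the ground-truth reduct family is every transversal that
picks one representative from each relevant/redundant duplicate group.

``make_statlog_like`` emulates the 13-attribute heart-disease schema
(kinds, domains, and the published marginal means/stds of the real
attributes) with a logistic class rule; it reproduces marginals and kinds
only, not the real joint distribution.  All tables here are synthetic
stand-ins generated from a seed — none contain patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .table import DecisionTable, MISSING, STATLOG_DOMAINS, STATLOG_KINDS

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "make_table",
    "inject_missing",
    "make_statlog_like",
    "random_table",
]


@dataclass
class SyntheticSpec:
    """Recipe for a planted-structure decision table.

    flip_noise is the probability that a label is flipped after the
    deterministic rule is applied; it must stay below 0.5 so the planted
    rule remains the Bayes rule.
    """

    n_objects: int = 200
    n_relevant: int = 2
    n_redundant: int = 1
    n_noise: int = 2
    flip_noise: float = 0.0
    #: "threshold" (class = 1 iff the level codes sum past the midpoint of the
    #: achievable range — additive risk, learnable by greedy trees), "parity"
    #: (pure interaction), "random" (seeded random tuple->class map), or an
    #: explicit tuple->class mapping.
    label_rule: str | dict = "threshold"
    seed: int = 0

    def __post_init__(self):
        if self.n_relevant < 1:
            raise ValueError("n_relevant must be >= 1")
        if not 0.0 <= self.flip_noise < 0.5:
            raise ValueError("flip_noise must lie in [0, 0.5)")


@dataclass
class GroundTruth:
    """What was planted: attribute roles and the minimal reducts."""

    roles: dict[str, str]                 # attribute -> relevant | redundant | noise
    duplicate_groups: list[list[str]]     # one group per relevant attribute
    reducts: list[frozenset] = field(default_factory=list)

    def is_reduct(self, candidate) -> bool:
        return frozenset(candidate) in set(self.reducts)


def _transversals(groups: list[list[str]]) -> list[frozenset]:
    out = [frozenset()]
    for g in groups:
        out = [r | {a} for r in out for a in g]
    return out


def make_table(spec: SyntheticSpec) -> tuple[DecisionTable, GroundTruth]:
    """Generate a planted-structure table and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_objects
    rel_names = [f"a{i + 1}" for i in range(spec.n_relevant)]
    # one shared level count (3 or 4) for the relevant attributes: under the
    # additive threshold rule an attribute with fewer levels than its peers
    # is only marginally informative, which would make the planted
    # relevance invisible to any marginal filter and the ground truth
    # ill-posed as a benchmark; equal levels keep the planted roles
    # symmetric and comparably detectable
    shared_levels = int(rng.integers(3, 5))
    levels = {a: shared_levels for a in rel_names}

    for _attempt in range(20):
        cols: dict[str, np.ndarray] = {
            a: rng.integers(0, levels[a], size=n) for a in rel_names
        }
        tuples = list(zip(*[cols[a] for a in rel_names]))
        if spec.label_rule == "threshold":
            smax = sum(levels[a] - 1 for a in rel_names)
            t_cut = int(np.ceil(smax / 2))
            labels = np.array([int(sum(t) >= t_cut) for t in tuples])
        elif spec.label_rule == "parity":
            labels = np.array([sum(t) % 2 for t in tuples])
        elif spec.label_rule == "random":
            domain = set(tuples)
            mapping = {t: int(rng.integers(0, 2)) for t in sorted(domain)}
            labels = np.array([mapping[t] for t in tuples])
        else:
            labels = np.array([spec.label_rule[t] for t in tuples])
        if 0 < labels.sum() < n:
            break
    else:
        raise RuntimeError("could not generate a two-class label vector")

    groups: list[list[str]] = [[a] for a in rel_names]
    roles = {a: "relevant" for a in rel_names}
    for j in range(spec.n_redundant):
        src = rel_names[j % spec.n_relevant]
        name = f"{src}_dup{j // spec.n_relevant + 1}"
        perm = rng.permutation(levels[src])
        cols[name] = perm[cols[src]]  # bijective relabeling: identical partition
        groups[j % spec.n_relevant].append(name)
        roles[name] = "redundant"
    for j in range(spec.n_noise):
        name = f"noise{j + 1}"
        k = int(rng.integers(2, 5))
        cols[name] = rng.integers(0, k, size=n)
        roles[name] = "noise"

    if spec.flip_noise > 0:
        flips = rng.random(n) < spec.flip_noise
        labels = np.where(flips, 1 - labels, labels)

    data = pd.DataFrame({a: pd.Series(v, dtype=object) for a, v in cols.items()})
    data["class"] = pd.Series(labels, dtype=object)
    # relevant/noise codes are graded levels (ordered); a permuted copy loses
    # the ordering, so redundant attributes are nominal
    kinds = {a: ("nominal" if roles.get(a) == "redundant" else "ordered") for a in cols}
    table = DecisionTable(data=data, decision="class", kinds=kinds)
    truth = GroundTruth(
        roles=roles,
        duplicate_groups=groups,
        reducts=_transversals(groups),
    )
    return table, truth


def inject_missing(table: DecisionTable, rate: float, seed: int = 0) -> DecisionTable:
    """Mask each condition cell independently with probability *rate*.

    The decision column is never masked.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    for a in table.condition_attributes:
        mask = rng.random(table.n_objects) < rate
        if table.kinds[a] == "real":
            col = out.data[a].astype(float).to_numpy()
            col[mask] = np.nan
            out.data[a] = col
        else:
            col = out.data[a].to_numpy(dtype=object, copy=True)
            col[mask] = MISSING
            out.data[a] = pd.Series(col, dtype=object, index=out.data.index)
    return out


# ---------------------------------------------------------------------------
# Statlog-like tables (synthetic stand-in for the heart-disease schema)
# ---------------------------------------------------------------------------

# (mean, std, low, high) for the real attributes, matching the published
# marginal summaries of the heart-disease schema
_REAL_MARGINALS = {
    "C1": (54.0, 9.0, 29.0, 77.0),
    "C4": (131.344, 17.862, 94.0, 200.0),
    "C5": (249.659, 51.686, 126.0, 564.0),
    "C8": (149.678, 23.1666, 71.0, 202.0),
    "C10": (1.05, 1.145, 0.0, 6.2),
}

# ST depression is zero-inflated in practice (no depression for many
# patients); a pure truncated normal cannot reach its published sd/mean
# ratio of 1.09, so a point mass at zero carries the excess dispersion
_ZERO_INFLATION = {"C10": 0.45}

# marginal category probabilities, chosen once as clinically plausible
_CAT_MARGINALS = {
    "C2": ([0, 1], [0.32, 0.68]),
    "C3": ([1, 2, 3, 4], [0.07, 0.16, 0.29, 0.48]),
    "C6": ([0, 1], [0.85, 0.15]),
    "C7": ([0, 1, 2], [0.49, 0.01, 0.50]),
    "C9": ([0, 1], [0.67, 0.33]),
    "C11": ([1, 2, 3], [0.48, 0.46, 0.06]),
    "C12": ([0, 1, 2, 3], [0.59, 0.21, 0.12, 0.08]),
    "C13": ([3, 6, 7], [0.56, 0.05, 0.39]),
}


def _matched_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """Truncated normal whose *truncated* mean/std match the targets.

    Truncation biases the moments (badly so when the target mean sits close
    to a bound, as for the ST-depression attribute), so the underlying
    location/scale are solved for numerically.
    """
    from scipy.optimize import fsolve

    def residual(params):
        loc, scale = params
        scale = abs(scale)
        d = truncnorm((lo - loc) / scale, (hi - loc) / scale, loc=loc, scale=scale)
        m, v = d.stats(moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    (loc, scale), _, ok, _ = fsolve(residual, [mean, sd], full_output=True)
    if ok != 1:  # fall back to the naive parameterization
        loc, scale = mean, sd
    scale = abs(scale)
    return truncnorm((lo - loc) / scale, (hi - loc) / scale, loc=loc, scale=scale)


def make_statlog_like(n: int, seed: int = 0) -> DecisionTable:
    """Synthetic table with the heart-disease schema (marginals only).

    Real attributes are truncated normals with the published means/stds;
    categorical attributes follow fixed plausible marginals; the class is
    assigned by a logistic rule over a subset of risk attributes, so the
    labels are noisy but learnable.  Schema-compatible with
    :func:`roughrelief.table.read_statlog` output.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    cols: dict[str, pd.Series] = {}
    for a, (mu, sd, lo, hi) in _REAL_MARGINALS.items():
        p0 = _ZERO_INFLATION.get(a, 0.0)
        if p0 > 0:
            # moment-match the continuous part given the point mass at lo
            m1 = (mu - p0 * lo) / (1 - p0)
            ex2 = sd**2 + mu**2
            v1 = (ex2 - p0 * lo**2) / (1 - p0) - m1**2
            dist = _matched_truncnorm(m1, float(np.sqrt(v1)), lo, hi)
            vals = dist.rvs(size=n, random_state=rng)
            vals[rng.random(n) < p0] = lo
        else:
            dist = _matched_truncnorm(mu, sd, lo, hi)
            vals = dist.rvs(size=n, random_state=rng)
        cols[a] = pd.Series(vals, dtype=float)
    for a, (vals, probs) in _CAT_MARGINALS.items():
        draws = rng.choice(len(vals), size=n, p=np.asarray(probs) / np.sum(probs))
        cols[a] = pd.Series([vals[d] for d in draws], dtype=object)

    # logistic risk score over a subset of attributes (fixed coefficients)
    logit = (
        -0.035 * (cols["C8"].astype(float) - 150.0)
        + 0.9 * (cols["C10"].astype(float) - 1.05)
        + 0.85 * cols["C12"].astype(float).to_numpy()
        + 1.1 * (cols["C9"].astype(float) == 1).to_numpy()
        + 1.2 * (cols["C13"].astype(float) != 3).to_numpy()
        + 0.9 * (cols["C3"].astype(float) == 4).to_numpy()
        + 0.5 * (cols["C2"].astype(float) == 1).to_numpy()
        - 2.2
    )
    p = 1.0 / (1.0 + np.exp(-np.asarray(logit, dtype=float)))
    labels = np.where(rng.random(n) < p, "presence", "absence")

    order = [f"C{i}" for i in range(1, 14)]
    data = pd.DataFrame({a: cols[a] for a in order})
    data["class"] = pd.Series(labels, dtype=object)
    domains = dict(STATLOG_DOMAINS)
    for a in _REAL_MARGINALS:
        vals = data[a].astype(float)
        domains[a] = (float(vals.min()), float(vals.max()))
    return DecisionTable(data=data, decision="class", kinds=dict(STATLOG_KINDS), domains=domains)


def random_table(
    n_objects: int, n_attributes: int, n_levels: int = 3, n_classes: int = 2, seed: int = 0
) -> DecisionTable:
    """Small uniformly random categorical table (property-test helper)."""
    rng = np.random.default_rng(seed)
    data = {
        f"x{j + 1}": pd.Series(rng.integers(0, n_levels, size=n_objects), dtype=object)
        for j in range(n_attributes)
    }
    data["class"] = pd.Series(rng.integers(0, n_classes, size=n_objects), dtype=object)
    df = pd.DataFrame(data)
    kinds = {f"x{j + 1}": "nominal" for j in range(n_attributes)}
    return DecisionTable(data=df, decision="class", kinds=kinds)
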