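"""Rough-set algebra and reduct discovery.

Implements the classical Pawlak machinery on decision tables:
indiscernibility partitions, lower/upper approximations, positive regions,
the dependency degree γ_P(Q) = |pos_P(Q)| / |U|, and attribute
significance.  Dependencies are compared through exact integer counts
(|pos| is an integer, |U| a fixed denominator), so reduct acceptance never
involves floating-point tolerance.

Two reduct finders are provided: an exhaustive subset scan usable as an
oracle on small attribute sets, and a genetic-algorithm search whose
initial population is biased by ReliefF weights — attributes ranked higher
by ReliefF are more likely to be switched on in initial chromosomes.
Every dependency-preserving chromosome the GA ever visits is reduced to a
minimal subset by greedy single-attribute deletion, so all returned
subsets are true reducts of the table.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .relieff import WeightVector
from .table import DecisionTable, is_missing

__all__ = [
    "Partition",
    "ApproximationPair",
    "ReductSet",
    "GAParams",
    "indiscernibility",
    "approximations",
    "positive_region",
    "dependency",
    "significance",
    "all_reducts_bruteforce",
    "ga_reduct_search",
    "GAReductSearch",
]

log = logging.getLogger(__name__)


@dataclass
class Partition:
    """Equivalence classes of an indiscernibility relation."""

    blocks: list[frozenset]

    def __iter__(self):
        return iter(self.blocks)

    def __len__(self):
        return len(self.blocks)


@dataclass
class ApproximationPair:
    lower: frozenset
    upper: frozenset


@dataclass
class ReductSet:
    """Minimal dependency-preserving attribute subsets."""

    reducts: list[frozenset]
    baseline_dependency: float

    def __iter__(self):
        return iter(self.reducts)

    def __len__(self):
        return len(self.reducts)

    def sizes(self) -> list[int]:
        return [len(r) for r in self.reducts]


@dataclass
class GAParams:
    population_size: int = 50
    generations: int = 100
    crossover_rate: float = 0.6
    mutation_rate: float = 0.02
    parsimony_weight: float = 0.1
    init_bias: tuple[float, float] = (0.1, 0.9)
    tournament_size: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_rate", "mutation_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Coded view of a table (categorical codes; MISSING = its own category)
# ---------------------------------------------------------------------------

class _Coded:
    """Integer-coded column view of a table for fast partition work."""

    def __init__(self, table: DecisionTable, attributes=None):
        attrs = attributes if attributes is not None else table.condition_attributes
        self.attrs = list(attrs)
        self.index = {a: i for i, a in enumerate(self.attrs)}
        n = table.n_objects
        self.n = n
        cols = []
        for a in self.attrs:
            col = table.data[a]
            codes = np.empty(n, dtype=np.int64)
            mapping: dict = {}
            vals = col.to_numpy()
            miss = col.isna().to_numpy()
            for i in range(n):
                key = "\0MISSING" if miss[i] else vals[i]
                codes[i] = mapping.setdefault(key, len(mapping))
            cols.append(codes)
        self.codes = np.column_stack(cols) if cols else np.zeros((n, 0), dtype=np.int64)
        dvals = table.decision_values()
        _, self.dcodes = np.unique(dvals, return_inverse=True)

    def groups(self, attr_idx: list[int]) -> dict[tuple, list[int]]:
        out: dict[tuple, list[int]] = {}
        sub = self.codes[:, attr_idx]
        for i in range(self.n):
            out.setdefault(tuple(sub[i]), []).append(i)
        return out

    def pos_count(self, attr_idx: tuple[int, ...]) -> int:
        """|pos_P(D)| for P given by column indices, in O(n * |P|)."""
        sub = self.codes[:, list(attr_idx)]
        state: dict[tuple, list] = {}
        for i in range(self.n):
            key = tuple(sub[i])
            rec = state.get(key)
            if rec is None:
                state[key] = [self.dcodes[i], 1, False]
            else:
                rec[1] += 1
                if rec[0] != self.dcodes[i]:
                    rec[2] = True
        return sum(cnt for _, cnt, conflict in state.values() if not conflict)


# ---------------------------------------------------------------------------
# Algebra
# ---------------------------------------------------------------------------

def _as_attr_list(P) -> list:
    return list(P)


def indiscernibility(table: DecisionTable, P) -> Partition:
    """Partition of U by identical value tuples on P (MISSING is a value)."""
    P = _as_attr_list(P)
    objs = table.objects
    if not P:
        log.info("indiscernibility: empty attribute set -> single block")
        return Partition([frozenset(objs)])
    coded = _Coded(table, attributes=P)
    groups = coded.groups(list(range(len(P))))
    blocks = [frozenset(objs[i] for i in idxs) for idxs in groups.values()]
    return Partition(blocks)


def approximations(table: DecisionTable, P, X) -> ApproximationPair:
    """Lower/upper approximation of object set X under Ind(P)."""
    X = frozenset(X)
    part = indiscernibility(table, P)
    lower = frozenset().union(*[b for b in part if b <= X]) if any(b <= X for b in part) else frozenset()
    upper = frozenset().union(*[b for b in part if b & X]) if any(b & X for b in part) else frozenset()
    return ApproximationPair(lower=lower, upper=upper)


def _decision_partition(table: DecisionTable, Q) -> list[frozenset]:
    Q = _as_attr_list(Q)
    objs = table.objects
    if all(q == table.decision for q in Q) and len(Q) == 1:
        groups: dict = {}
        for obj, v in zip(objs, table.decision_values()):
            groups.setdefault(v, []).append(obj)
        return [frozenset(v) for v in groups.values()]
    # general Q: group by value tuples over (possibly condition) attributes
    cols = [table.data[q].to_numpy() for q in Q]
    groups = {}
    for i, obj in enumerate(objs):
        key = tuple("\0MISSING" if is_missing(c[i]) else c[i] for c in cols)
        groups.setdefault(key, []).append(obj)
    return [frozenset(v) for v in groups.values()]


def positive_region(table: DecisionTable, P, Q) -> frozenset:
    """Union of P-lower approximations of the Q-equivalence classes."""
    blocks = _decision_partition(table, Q)
    pos: set = set()
    part = indiscernibility(table, P)
    for b in part:
        for X in blocks:
            if b <= X:
                pos |= b
                break
    return frozenset(pos)


def dependency(table: DecisionTable, P, Q) -> float:
    """γ_P(Q) = |pos_P(Q)| / |U|, in [0, 1]."""
    return len(positive_region(table, P, Q)) / table.n_objects


def significance(table: DecisionTable, P, Q, a) -> float:
    """Dependency drop from removing attribute *a* out of P."""
    P = _as_attr_list(P)
    if a not in P:
        raise ValueError(f"attribute {a!r} is not a member of P")
    rest = [x for x in P if x != a]
    return dependency(table, P, Q) - dependency(table, rest, Q)


# ---------------------------------------------------------------------------
# Exhaustive reducts (oracle)
# ---------------------------------------------------------------------------

def all_reducts_bruteforce(table: DecisionTable, max_attributes: int = 15) -> ReductSet:
    """All minimal dependency-preserving subsets by exhaustive scan.

    Scans subsets in order of increasing size, keeping those that reach the
    full-set dependency and contain no previously kept reduct; by the
    monotonicity of γ this yields exactly the subset-minimal preservers.
    """
    attrs = table.condition_attributes
    if len(attrs) > max_attributes:
        raise ValueError(
            f"{len(attrs)} attributes exceed the exhaustive-scan limit of {max_attributes}"
        )
    coded = _Coded(table)
    full = coded.pos_count(tuple(range(len(attrs))))
    found: list[tuple[int, ...]] = []
    for size in range(1, len(attrs) + 1):
        for combo in itertools.combinations(range(len(attrs)), size):
            cset = set(combo)
            if any(set(r) <= cset for r in found):
                continue
            if coded.pos_count(combo) == full:
                found.append(combo)
    reducts = [frozenset(attrs[i] for i in combo) for combo in found]
    return ReductSet(reducts=reducts, baseline_dependency=full / table.n_objects)


# ---------------------------------------------------------------------------
# GA search
# ---------------------------------------------------------------------------

def _minimize(mask_idx: tuple[int, ...], coded: _Coded, full: int, weight_order: list[int]) -> frozenset:
    """Greedy single-deletion minimization, lowest-ReliefF-weight first."""
    current = set(mask_idx)
    changed = True
    while changed:
        changed = False
        for j in weight_order:  # ascending weight
            if j in current and len(current) > 1:
                trial = tuple(sorted(current - {j}))
                if coded.pos_count(trial) == full:
                    current.remove(j)
                    changed = True
    return frozenset(current)


def ga_reduct_search(
    table: DecisionTable,
    wv: WeightVector,
    params: GAParams | None = None,
) -> ReductSet:
    """GA reduct search seeded by ReliefF weights.

    Chromosomes are inclusion bitmasks over the condition attributes.  The
    initial per-bit activation probability is the min–max-normalized
    ReliefF weight clipped to ``params.init_bias``.  Fitness is
    ``γ_P(D)/γ_C(D) − λ·|P|/|C|`` with a +1 bonus for exact dependency
    preservation, which makes preserving individuals strictly dominate all
    non-preserving ones.  Tournament selection, uniform crossover, bit-flip
    mutation and single-individual elitism; every preserving individual
    encountered in any generation is minimized and accumulated.
    Deterministic given ``params.seed``.
    """
    params = params or GAParams()
    attrs = table.condition_attributes
    m = len(attrs)
    for a in attrs:
        if a not in wv.weights:
            raise ValueError(f"weight vector is missing attribute {a!r}")
    coded = _Coded(table)
    full = coded.pos_count(tuple(range(m)))
    if full == 0:
        raise ValueError("decision independent of conditions (gamma_C(D) = 0)")

    w = np.array([wv.weights[a] for a in attrs], dtype=float)
    span = w.max() - w.min()
    wnorm = (w - w.min()) / span if span > 0 else np.full(m, 0.5)
    lo, hi = params.init_bias
    p_init = np.clip(wnorm, lo, hi)
    top_bit = int(np.argmax(w))
    weight_order = list(np.argsort(w, kind="stable"))  # ascending

    rng = np.random.default_rng(params.seed)
    lam = params.parsimony_weight

    cache: dict[tuple, int] = {}

    def pos(mask: np.ndarray) -> int:
        key = tuple(np.flatnonzero(mask))
        if key not in cache:
            cache[key] = coded.pos_count(key)
        return cache[key]

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[top_bit] = True
        return mask

    def fitness(mask: np.ndarray) -> float:
        p = pos(mask)
        f = p / full - lam * mask.sum() / m
        if p == full:
            f += 1.0
        return f

    population = [repair(rng.random(m) < p_init) for _ in range(params.population_size)]
    preserving: set[tuple] = set()

    def harvest(pop):
        for mask in pop:
            if pos(mask) == full:
                preserving.add(tuple(np.flatnonzero(mask)))

    harvest(population)
    for _gen in range(params.generations):
        fits = np.array([fitness(ind) for ind in population])
        # elitism: best fitness, ties -> fewer attributes, then lexicographic
        elite_idx = min(
            range(len(population)),
            key=lambda i: (-fits[i], population[i].sum(), tuple(population[i])),
        )
        new_pop = [population[elite_idx].copy()]
        while len(new_pop) < params.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, len(population), size=params.tournament_size)
                best = max(contenders, key=lambda i: fits[i])
                parents.append(population[best])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < params.crossover_rate:
                swap = rng.random(m) < 0.5
                c1[swap], c2[swap] = parents[1][swap], parents[0][swap]
            for child in (c1, c2):
                flip = rng.random(m) < params.mutation_rate
                child ^= flip
                new_pop.append(repair(child))
                if len(new_pop) >= params.population_size:
                    break
        population = new_pop
        harvest(population)

    minimal: set[frozenset] = set()
    for mask_idx in sorted(preserving):
        minimal.add(_minimize(mask_idx, coded, full, weight_order))
    # safety superset filter (minimization already guarantees minimality)
    final = [r for r in minimal if not any(o < r for o in minimal)]
    reducts = sorted(
        (frozenset(attrs[i] for i in r) for r in final),
        key=lambda s: (len(s), sorted(attrs.index(a) for a in s)),
    )
    return ReductSet(reducts=reducts, baseline_dependency=full / table.n_objects)


class GAReductSearch(BaseEstimator):
    """Estimator wrapper over :func:`ga_reduct_search`.

    ``fit`` expects the decision table plus a ReliefF :class:`WeightVector`
    (or a plain attribute→weight mapping) to bias initialization.

    Attributes
    ----------
    reducts_ : list of frozenset
    baseline_dependency_ : float
    """

    def __init__(self, population_size=50, generations=100, crossover_rate=0.6,
                 mutation_rate=0.02, parsimony_weight=0.1, init_bias=(0.1, 0.9),
                 tournament_size=2, random_state=0):
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.parsimony_weight = parsimony_weight
        self.init_bias = init_bias
        self.tournament_size = tournament_size
        self.random_state = random_state

    def fit(self, table: DecisionTable, y=None, weights: WeightVector | dict | None = None):
        if weights is None:
            weights = WeightVector(
                weights={a: 0.0 for a in table.condition_attributes},
                k_neighbors=0, n_samples=None,
            )
        elif isinstance(weights, dict):
            weights = WeightVector(weights=dict(weights), k_neighbors=0, n_samples=None)
        params = GAParams(
            population_size=self.population_size,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            parsimony_weight=self.parsimony_weight,
            init_bias=tuple(self.init_bias),
            tournament_size=self.tournament_size,
            seed=self.random_state,
        )
        result = ga_reduct_search(table, weights, params)
        self.reduct_set_ = result
        self.reducts_ = list(result.reducts)
        self.baseline_dependency_ = result.baseline_dependency
        return self
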