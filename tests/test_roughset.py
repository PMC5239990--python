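"""Rough-set algebra, exhaustive reducts, and the GA search."""

import itertools

import numpy as np
import pytest

from roughrelief.relieff import WeightVector, relieff_weights
from roughrelief.roughset import (
    GAParams,
    all_reducts_bruteforce,
    approximations,
    dependency,
    ga_reduct_search,
    indiscernibility,
    positive_region,
    significance,
)
from roughrelief.synthetic import SyntheticSpec, make_table, random_table
from conftest import make_decision_table


def uniform_wv(table):
    return WeightVector(
        weights={a: 0.0 for a in table.condition_attributes}, k_neighbors=0, n_samples=None
    )


def dependency_oracle(table, P, Q):
    """Brute-force dependency: pairwise indiscernibility, per-block checks."""
    objs = table.objects

    def key(obj, attrs):
        vals = []
        for a in attrs:
            v = table.data.loc[obj, a]
            vals.append("NA" if (v is None or (isinstance(v, float) and np.isnan(v)) or v is np.nan or str(v) == "<NA>") else v)
        return tuple(vals)

    blocks = {}
    for o in objs:
        blocks.setdefault(key(o, P), []).append(o)
    qblocks = {}
    for o in objs:
        qblocks.setdefault(key(o, Q), []).append(o)
    pos = 0
    for b in blocks.values():
        for qb in qblocks.values():
            if set(b) <= set(qb):
                pos += len(b)
                break
    return pos / len(objs)


class TestAlgebra:
    def test_partition_groups_equal_tuples(self, five_object_table):
        part = indiscernibility(five_object_table, ["x"])
        blocks = {frozenset(b) for b in part}
        assert blocks == {frozenset({0, 1}), frozenset({2, 3, 4})}

    def test_all_distinct_rows_give_singletons(self):
        table = make_decision_table(
            {"a": [0, 1, 2, 3, 4], "class": [0, 1, 0, 1, 0]}, {"a": "nominal"}
        )
        part = indiscernibility(table, ["a"])
        assert sorted(len(b) for b in part) == [1, 1, 1, 1, 1]

    def test_adding_attribute_refines_partition(self):
        for seed in range(10):
            table = random_table(15, 3, seed=seed)
            part1 = indiscernibility(table, ["x1"])
            part2 = indiscernibility(table, ["x1", "x2"])
            for b2 in part2:
                assert any(b2 <= b1 for b1 in part1)

    def test_approximations_full_and_empty(self, five_object_table):
        U = set(five_object_table.objects)
        ap = approximations(five_object_table, ["x"], U)
        assert ap.lower == ap.upper == frozenset(U)
        ap0 = approximations(five_object_table, ["x"], set())
        assert ap0.lower == ap0.upper == frozenset()

    def test_approximations_hand_example(self, five_object_table):
        # blocks {0,1}, {2,3,4}; X = {1,2,3,4}
        ap = approximations(five_object_table, ["x"], {1, 2, 3, 4})
        assert ap.lower == frozenset({2, 3, 4})
        assert ap.upper == frozenset({0, 1, 2, 3, 4})
        assert ap.lower <= frozenset({1, 2, 3, 4}) <= ap.upper

    def test_positive_region_example(self, five_object_table):
        pos = positive_region(five_object_table, ["x"], ["class"])
        assert pos == frozenset({2, 3, 4})

    def test_positive_region_constant_decision(self):
        table = make_decision_table(
            {"a": [0, 1, 0], "class": [1, 1, 1]}, {"a": "nominal"}
        )
        assert positive_region(table, ["a"], ["class"]) == frozenset(table.objects)

    def test_dependency_example(self, five_object_table):
        assert dependency(five_object_table, ["x"], ["class"]) == pytest.approx(0.6)

    def test_dependency_one_on_consistent_table(self):
        table = make_decision_table(
            {"a": [0, 1, 2], "class": ["x", "y", "z"]}, {"a": "nominal"}
        )
        assert dependency(table, ["a"], ["class"]) == 1.0

    def test_duplicated_attribute_changes_nothing(self):
        table = make_decision_table(
            {"a": [0, 1, 1, 0], "a2": [5, 7, 7, 5], "class": [0, 1, 1, 1]},
            {"a": "nominal", "a2": "nominal"},
        )
        d1 = dependency(table, ["a"], ["class"])
        d2 = dependency(table, ["a", "a2"], ["class"])
        assert d1 == d2
        assert significance(table, ["a", "a2"], ["class"], "a2") == 0.0

    def test_significance_requires_membership(self, five_object_table):
        with pytest.raises(ValueError):
            significance(five_object_table, ["x"], ["class"], "not-there")

    def test_significance_single_determining_attribute(self):
        table = make_decision_table(
            {"a": [0, 1, 2, 0], "class": ["x", "y", "z", "x"]}, {"a": "nominal"}
        )
        # r_{a} = 1; r_empty = 0 (one block, mixed labels)
        assert significance(table, ["a"], ["class"], "a") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(15))
    def test_algebra_matches_bruteforce_oracle(self, seed):
        table = random_table(12, 3, n_levels=2, seed=seed)
        attrs = table.condition_attributes
        for r in range(1, 3):
            for P in itertools.combinations(attrs, r):
                assert dependency(table, list(P), ["class"]) == pytest.approx(
                    dependency_oracle(table, list(P), ["class"])
                )
        for a in attrs:
            sig = significance(table, attrs, ["class"], a)
            rest = [x for x in attrs if x != a]
            assert sig == pytest.approx(
                dependency_oracle(table, attrs, ["class"])
                - dependency_oracle(table, rest, ["class"])
            )
            assert sig >= -1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_monotonicity_of_positive_region(self, seed):
        table = random_table(20, 4, seed=seed)
        attrs = table.condition_attributes
        rng = np.random.default_rng(seed)
        small = list(rng.choice(attrs, size=2, replace=False))
        big = small + [a for a in attrs if a not in small][:1]
        pos_small = positive_region(table, small, ["class"])
        pos_big = positive_region(table, big, ["class"])
        assert pos_small <= pos_big
        assert dependency(table, small, ["class"]) <= dependency(table, big, ["class"])


class TestBruteForce:
    def test_duplicate_attribute_yields_two_reducts(self):
        spec = SyntheticSpec(n_objects=120, n_relevant=2, n_redundant=1, n_noise=2, seed=3)
        table, truth = make_table(spec)
        rs = all_reducts_bruteforce(table)
        assert set(rs.reducts) == set(truth.reducts)

    def test_single_determining_attribute(self):
        spec = SyntheticSpec(n_objects=150, n_relevant=1, n_redundant=0, n_noise=3, seed=8)
        table, truth = make_table(spec)
        rs = all_reducts_bruteforce(table)
        assert rs.reducts == truth.reducts
        assert len(rs.reducts[0]) == 1

    def test_full_set_always_contains_a_reduct(self):
        for seed in range(5):
            table = random_table(15, 4, seed=seed)
            rs = all_reducts_bruteforce(table)
            assert len(rs.reducts) >= 1

    def test_reducts_are_minimal(self):
        table = random_table(25, 5, seed=1)
        rs = all_reducts_bruteforce(table)
        base = rs.baseline_dependency
        for r in rs.reducts:
            assert dependency(table, r, ["class"]) == pytest.approx(base)
            for a in r:
                if len(r) > 1:
                    smaller = dependency(table, r - {a}, ["class"])
                    assert smaller < base

    def test_attribute_limit_enforced(self):
        table = random_table(10, 4, seed=0)
        with pytest.raises(ValueError, match="exceed"):
            all_reducts_bruteforce(table, max_attributes=3)


class TestGASearch:
    def test_outputs_contained_in_bruteforce(self):
        params = GAParams(population_size=20, generations=15, seed=5)
        for seed in range(20):
            table = random_table(20, 5, seed=seed)
            oracle = set(all_reducts_bruteforce(table).reducts)
            found = ga_reduct_search(table, uniform_wv(table), params)
            assert set(found.reducts) <= oracle
            assert len(found.reducts) >= 1

    def test_single_determining_attribute_found_exactly(self):
        spec = SyntheticSpec(n_objects=200, n_relevant=1, n_redundant=0, n_noise=7, seed=6)
        table, truth = make_table(spec)
        wv = relieff_weights(table, k_neighbors=5)
        found = ga_reduct_search(table, wv, GAParams(seed=2))
        assert found.reducts == truth.reducts

    def test_deterministic_given_seed(self):
        table = random_table(25, 6, seed=4)
        wv = uniform_wv(table)
        a = ga_reduct_search(table, wv, GAParams(population_size=16, generations=10, seed=9))
        b = ga_reduct_search(table, wv, GAParams(population_size=16, generations=10, seed=9))
        assert a.reducts == b.reducts

    def test_minimality_of_results(self):
        table = random_table(30, 6, seed=12)
        found = ga_reduct_search(
            table, uniform_wv(table), GAParams(population_size=20, generations=15, seed=0)
        )
        base = found.baseline_dependency
        for r in found.reducts:
            for a in r:
                if len(r) > 1:
                    assert dependency(table, r - {a}, ["class"]) < base

    def test_degenerate_decision_rejected(self):
        # decision varies inside every block -> empty positive region
        table = make_decision_table(
            {"a": [0, 0, 1, 1], "class": [0, 1, 0, 1]}, {"a": "nominal"}
        )
        with pytest.raises(ValueError, match="independent"):
            ga_reduct_search(table, uniform_wv(table), GAParams(seed=0))
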