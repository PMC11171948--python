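"""Decision-tree engine: validation, rollback, enumeration, microsimulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppdcea.synthetic import ToyTreeSpec, make_toy_tree
from ppdcea.tree import (
    Branch, TreeError, chance, decision, enumerate_paths, evaluate,
    from_dict, microsimulate, rollback, terminal, to_dict, trees_equal, validate,
)


def two_level_binary():
    """p=0.3/0.7 then p=0.5/0.5; costs on branches, effects at leaves."""
    lower = chance("flip2", [
        Branch("heads", "0.5", "10", terminal("a", "0", "1.0", "a")),
        Branch("tails", "0.5", "0", terminal("b", "100", "0.0", "b")),
    ])
    return chance("flip1", [
        Branch("left", "0.3", "5", lower),
        Branch("right", "0.7", "0", terminal("c", "20", "0.5", "c")),
    ])


class TestExpressions:
    def test_arithmetic_over_names(self):
        assert evaluate("1 - p * (a + b)", {"p": 0.5, "a": 1, "b": 3}) == -1.0

    def test_disallowed_constructs_rejected(self):
        for expr in ("__import__('os')", "p ** 2", "p[0]", "f(1)", "'x'"):
            with pytest.raises(TreeError):
                evaluate(expr, {"p": 1.0})

    def test_unknown_name_reported(self):
        with pytest.raises(TreeError, match="unknown name"):
            evaluate("p_missing", {})


class TestValidate:
    def test_single_terminal_is_valid(self):
        assert validate(terminal("t", "0", "1", "x"), {}).ok

    def test_probability_sum_violation_reported(self):
        bad = chance("c", [
            Branch("a", "0.6", "0", terminal("a", "0", "1", "a")),
            Branch("b", "0.6", "0", terminal("b", "0", "0", "b")),
        ])
        report = validate(bad, {})
        assert not report.ok
        assert any("sum" in e for e in report.errors)

    def test_decision_below_root_is_error(self):
        inner = decision("d", [Branch("x", None, "0", terminal("t", "0", "1", "x"))])
        tree = chance("c", [Branch("go", "1.0", "0", inner)])
        report = validate(tree, {})
        assert any("below root" in e for e in report.errors)

    def test_unreachable_branch_warned(self):
        tree = chance("c", [
            Branch("a", "1.0", "0", terminal("a", "0", "1", "a")),
            Branch("b", "0.0", "0", terminal("b", "0", "0", "b")),
        ])
        report = validate(tree, {})
        assert report.ok
        assert any("unreachable" in w for w in report.warnings)

    def test_strategy_trees_validate(self, trees, env):
        for name, tree in trees.items():
            report = validate(tree, env)
            assert report.ok, (name, report.errors)

    def test_cycle_is_hard_error(self):
        a = chance("a", [])
        b = chance("b", [Branch("back", "1.0", "0", a)])
        a.branches.append(Branch("fwd", "1.0", "0", b))
        with pytest.raises(TreeError, match="cycle"):
            validate(a, {})


class TestRollback:
    def test_terminal_identity(self):
        assert rollback(terminal("t", "10", "0.5", "x"), {}) == (10.0, 0.5)

    def test_symmetric_chance_node(self):
        tree = chance("c", [
            Branch("a", "0.5", "0", terminal("a", "0", "1.0", "a")),
            Branch("b", "0.5", "0", terminal("b", "100", "0.0", "b")),
        ])
        assert rollback(tree, {}) == (50.0, 0.5)

    def test_branch_costs_accrue_along_paths(self):
        cost, effect = rollback(two_level_binary(), {})
        # left: 5 + 0.5*(10+0) + 0.5*(0+100); right: 20
        assert cost == pytest.approx(0.3 * (5 + 0.5 * 10 + 0.5 * 100) + 0.7 * 20)
        assert effect == pytest.approx(0.3 * 0.5 + 0.7 * 0.5)

    def test_decision_node_rejected(self):
        tree = decision("d", [Branch("x", None, "0", terminal("t", "0", "1", "x"))])
        with pytest.raises(TreeError, match="decision"):
            rollback(tree, {})


class TestEnumeratePaths:
    def test_single_terminal_single_path(self):
        paths = enumerate_paths(terminal("t", "3", "0.9", "x"), {})
        assert len(paths) == 1
        assert paths[0].prob == 1.0 and paths[0].cost == 3.0

    def test_two_level_tree_path_partition(self):
        paths = enumerate_paths(two_level_binary(), {})
        assert len(paths) == 3
        assert sum(p.prob for p in paths) == pytest.approx(1.0, abs=1e-12)

    def test_aggregation_equals_rollback(self, trees, env):
        for tree in trees.values():
            paths = enumerate_paths(tree, env)
            assert sum(p.prob for p in paths) == pytest.approx(1.0, abs=1e-9)
            c, e = rollback(tree, env)
            assert sum(p.prob * p.cost for p in paths) == pytest.approx(c, abs=1e-9)
            assert sum(p.prob * p.effect for p in paths) == pytest.approx(e, abs=1e-9)


class TestMicrosimulate:
    def test_single_path_tree_is_exact(self):
        tree = chance("only", [Branch("go", "1.0", "7", terminal("t", "3", "0.25", "x"))])
        res = microsimulate(tree, {}, 500, seed=0)
        assert res.mean_cost == pytest.approx(10.0)
        assert res.mean_effect == pytest.approx(0.25)
        assert res.counts == {"x": 500}

    def test_fair_split_within_binomial_bound(self):
        tree = chance("flip", [
            Branch("a", "0.5", "0", terminal("a", "0", "1", "a")),
            Branch("b", "0.5", "0", terminal("b", "0", "0", "b")),
        ])
        res = microsimulate(tree, {}, 10_000, seed=5)
        assert abs(res.counts["a"] - 5_000) < 3 * math.sqrt(10_000 * 0.25)

    def test_mean_within_clt_band_of_rollback(self):
        tree, exp_cost, exp_effect = make_toy_tree(ToyTreeSpec(depth=3, seed=2))
        paths = enumerate_paths(tree, {})
        var = sum(p.prob * p.cost**2 for p in paths) - exp_cost**2
        n = 100_000
        res = microsimulate(tree, {}, n, seed=3)
        assert abs(res.mean_cost - exp_cost) < 4 * math.sqrt(var / n)

    def test_counts_sum_to_cohort_size(self, trees, env):
        res = microsimulate(trees["routine_care"], env, 2_345, seed=9)
        assert sum(res.counts.values()) == 2_345

    def test_same_seed_bitwise_identical(self, trees, env):
        a = microsimulate(trees["early_postnatal_screening"], env, 4_000, seed=17)
        b = microsimulate(trees["early_postnatal_screening"], env, 4_000, seed=17)
        assert a == b

    def test_shared_labels_couple_across_trees(self, trees, env):
        # the PPD-onset draw is shared: with one seed, the same women develop
        # PPD in every arm, the common-random-numbers contract
        r = microsimulate(trees["routine_care"], env, 8_000, seed=21)
        s = microsimulate(trees["early_postnatal_screening"], env, 8_000, seed=21)
        n_ppd_r = r.n - r.counts["no_ppd"]
        n_ppd_s = s.n - s.counts["no_ppd"]
        assert n_ppd_r == n_ppd_s

    def test_rejects_empty_cohort(self, trees, env):
        with pytest.raises(TreeError):
            microsimulate(trees["routine_care"], env, 0, seed=0)


class TestSerialization:
    def test_round_trip_is_lossless(self, trees, tmp_path):
        for name, tree in trees.items():
            doc = to_dict(tree)
            again = from_dict(doc)
            assert trees_equal(tree, again), name


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(0, 10_000), st.integers(1, 4), st.integers(2, 3))
def test_rollback_equals_enumeration_on_random_trees(seed, depth, branching):
    """Bottom-up expectation must equal brute-force path aggregation."""
    tree, exp_cost, exp_effect = make_toy_tree(ToyTreeSpec(depth=depth, branching=branching, seed=seed))
    c, e = rollback(tree, {})
    paths = enumerate_paths(tree, {})
    assert c == pytest.approx(sum(p.prob * p.cost for p in paths), abs=1e-9)
    assert e == pytest.approx(sum(p.prob * p.effect for p in paths), abs=1e-9)
    assert c == pytest.approx(exp_cost, abs=1e-9)
    assert e == pytest.approx(exp_effect, abs=1e-9)
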