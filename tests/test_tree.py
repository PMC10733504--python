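"""Tree engine: validation, rollback, comparison, microsimulation."""

import numpy as np
import pytest

from deafcea.model import ModelVariant, build_screening_tree, build_status_quo_tree
from deafcea.tree import (
    PAYOFF_KEYS,
    Branch,
    ChanceNode,
    DecisionTree,
    StrategyResult,
    TerminalNode,
    compare,
    microsimulate,
    rollback,
    strategy_result,
    tree_from_dict,
    tree_to_dict,
    validate_tree,
)


def leaf(outcome="healthy_birth", cost=0.0, utility=0.0):
    return TerminalNode(
        outcome,
        {
            "cost": cost,
            "eff_deaf": 1.0 if outcome == "deaf_birth" else 0.0,
            "eff_healthy": 1.0 if outcome == "healthy_birth" else 0.0,
            "eff_utility": utility,
        },
    )


def brute_force_expectation(tree, key):
    """Independent oracle: explicit stack-based path enumeration."""
    total = 0.0
    stack = [(tree.root, 1.0)]
    while stack:
        node, prob = stack.pop()
        if isinstance(node, TerminalNode):
            total += prob * node.payoffs[key]
        else:
            for b in node.branches:
                stack.append((b.child, prob * b.probability))
    return total


def random_tree(rng, depth=3):
    """Random small multi-payoff tree for property checks."""
    if depth == 0 or rng.random() < 0.3:
        outcome = ("healthy_birth", "deaf_birth", "no_birth")[rng.integers(3)]
        return leaf(outcome, cost=float(rng.normal(100, 50)), utility=float(rng.random() * 20))
    k = int(rng.integers(2, 4))
    probs = rng.dirichlet(np.ones(k))
    return ChanceNode(
        [Branch(float(p), random_tree(rng, depth - 1), f"b{i}") for i, p in enumerate(probs)]
    )


class TestValidation:
    def test_single_terminal_root_is_valid(self):
        assert validate_tree(DecisionTree(leaf(), "t")) == []

    def test_probability_sum_violation_reported(self):
        bad = ChanceNode([Branch(0.6, leaf(), "a"), Branch(0.5, leaf(), "b")])
        report = validate_tree(DecisionTree(bad, "bad"))
        assert len(report) == 1 and "sum" in report[0]

    @pytest.mark.parametrize("variant", list(ModelVariant))
    def test_constructed_strategy_trees_are_valid(self, params, variant):
        assert validate_tree(build_status_quo_tree(params, variant)) == []
        assert validate_tree(build_screening_tree(params, variant)) == []


class TestRollback:
    def test_terminal_rollback_returns_payoff(self):
        assert rollback(DecisionTree(leaf(cost=5.0)), "cost") == 5.0

    def test_two_branch_expectation(self):
        t = DecisionTree(
            ChanceNode([Branch(0.3, leaf("deaf_birth"), "d"), Branch(0.7, leaf(), "h")])
        )
        assert rollback(t, "eff_deaf") == pytest.approx(0.3)

    def test_unknown_key_raises(self):
        with pytest.raises(KeyError):
            rollback(DecisionTree(leaf()), "eff_bogus")

    def test_status_quo_deaf_probability(self, params):
        t = build_status_quo_tree(params, ModelVariant.DEAF_COUNT)
        assert rollback(t, "eff_deaf") == pytest.approx(0.0073, abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rollback_matches_brute_force_oracle(self, params, seed):
        rng = np.random.default_rng(seed)
        trees = [DecisionTree(random_tree(rng), f"rand{seed}")]
        trees += [build_screening_tree(params, v) for v in ModelVariant]
        for t in trees:
            for key in PAYOFF_KEYS:
                assert rollback(t, key) == pytest.approx(
                    brute_force_expectation(t, key), rel=1e-12, abs=1e-15
                )

    def test_cost_rollback_is_linear_in_terminal_costs(self, params):
        t = build_screening_tree(params, ModelVariant.DEAF_COUNT)
        base = rollback(t, "cost")

        def scale(node, k):
            if isinstance(node, TerminalNode):
                node.payoffs["cost"] *= k
            else:
                for b in node.branches:
                    scale(b.child, k)

        scale(t.root, 3.0)
        assert rollback(t, "cost") == pytest.approx(3.0 * base, rel=1e-12)


class TestStrategyResultAndCompare:
    def test_outcome_mass_conserved_and_indicators_consistent(self, params):
        for variant in ModelVariant:
            for build in (build_status_quo_tree, build_screening_tree):
                res = strategy_result(build(params, variant))
                assert sum(res.outcome_mass.values()) == pytest.approx(1.0, abs=1e-9)
                assert res.expected["eff_deaf"] == pytest.approx(
                    res.outcome_mass["deaf_birth"], abs=1e-12
                )
                assert res.expected["eff_healthy"] == pytest.approx(
                    res.outcome_mass["healthy_birth"], abs=1e-12
                )

    def test_status_quo_has_no_childless_path(self, params):
        res = strategy_result(build_status_quo_tree(params, ModelVariant.DEAF_COUNT))
        assert res.outcome_mass["no_birth"] == 0.0

    def test_icer_from_published_increments(self):
        # dC = 166.60 on dE = +0.0001384 healthy births -> about 1.2M per birth
        ref = StrategyResult("sq", {"cost": 651.0, "eff_healthy": 0.9927}, {})
        alt = StrategyResult("sc", {"cost": 817.60, "eff_healthy": 0.9927 + 0.0001384}, {})
        cmp_ = compare(ref, alt, "eff_healthy")
        assert cmp_.dominance == "tradeoff_icer"
        assert cmp_.icer == pytest.approx(1_203_926, rel=1e-3)

    def test_costlier_and_less_effective_is_dominated(self):
        ref = StrategyResult("sq", {"cost": 100.0, "eff_deaf": 0.5}, {})
        alt = StrategyResult("sc", {"cost": 150.0, "eff_deaf": 0.4}, {})
        cmp_ = compare(ref, alt, "eff_deaf")
        assert cmp_.dominance == "alt_dominated"
        assert cmp_.icer is None
        assert cmp_.cost_per_case_averted == pytest.approx(500.0)

    def test_self_comparison_is_all_zero(self, params):
        res = strategy_result(build_screening_tree(params, ModelVariant.DEAF_COUNT))
        cmp_ = compare(res, res, "eff_deaf")
        assert cmp_.delta_cost == 0.0 and cmp_.delta_eff == 0.0 and cmp_.icer is None


class TestMicrosimulation:
    def test_single_terminal_is_exact_with_zero_se(self):
        t = DecisionTree(leaf(cost=7.0, utility=3.0), "t")
        res = microsimulate(t, 1, seed=0)
        assert res.expected["cost"] == 7.0 and res.se["cost"] == 0.0

    def test_same_seed_reproduces_output(self, params):
        t = build_screening_tree(params, ModelVariant.DEAF_COUNT)
        a = microsimulate(t, 5000, seed=11)
        b = microsimulate(t, 5000, seed=11)
        assert a.expected == b.expected and a.outcome_mass == b.outcome_mass

    def test_empirical_means_within_three_se_of_rollback(self, params):
        t = build_status_quo_tree(params, ModelVariant.DEAF_COUNT)
        res = microsimulate(t, 50_000, seed=1234)
        for key in PAYOFF_KEYS:
            exact = rollback(t, key)
            tol = 3 * res.se[key] if res.se[key] > 0 else 1e-12
            assert abs(res.expected[key] - exact) <= tol


class TestSerialization:
    def test_json_roundtrip_preserves_rollback(self, params):
        t = build_screening_tree(params, ModelVariant.UTILITY)
        t2 = tree_from_dict(tree_to_dict(t))
        for key in PAYOFF_KEYS:
            assert rollback(t2, key) == rollback(t, key)
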