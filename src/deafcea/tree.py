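"""Generic multi-payoff decision-tree engine.

Trees are built from :class:`ChanceNode` and :class:`TerminalNode` objects.
Every terminal carries the full payoff vector (cost plus the three
effectiveness measures), so a single tree supports rollback under any payoff
key.  Strategies are represented as separate trees and compared externally
via :func:`compare` (incremental cost, incremental effect, ICER, dominance).

:func:`microsimulate` samples individual root-to-leaf paths with sequential
inverse-CDF draws at each chance node; it serves as a stochastic oracle for
the analytic rollback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Union

import numpy as np

__all__ = [
    "PAYOFF_KEYS",
    "OUTCOME_LABELS",
    "TerminalNode",
    "ChanceNode",
    "Branch",
    "DecisionTree",
    "StrategyResult",
    "CEAComparison",
    "MicrosimResult",
    "validate_tree",
    "rollback",
    "enumerate_paths",
    "strategy_result",
    "compare",
    "microsimulate",
    "tree_to_dict",
    "tree_from_dict",
]

PAYOFF_KEYS = ("cost", "eff_deaf", "eff_healthy", "eff_utility")
OUTCOME_LABELS = ("healthy_birth", "deaf_birth", "no_birth")

_PROB_TOL = 1e-9


@dataclass
class TerminalNode:
    """Leaf outcome with its payoff vector.

    ``eff_deaf`` and ``eff_healthy`` are 0/1 indicators of the outcome
    label; ``eff_utility`` is the lifetime QALY of the born individual
    (0 for no birth).
    """

    outcome_label: str
    payoffs: dict[str, float]

    def __post_init__(self) -> None:
        if self.outcome_label not in OUTCOME_LABELS:
            raise ValueError(f"unknown outcome label {self.outcome_label!r}")
        missing = [k for k in PAYOFF_KEYS if k not in self.payoffs]
        if missing:
            raise ValueError(f"terminal missing payoff keys {missing}")
        if self.payoffs["eff_deaf"] not in (0.0, 1.0) or self.payoffs[
            "eff_healthy"
        ] not in (0.0, 1.0):
            raise ValueError("eff_deaf / eff_healthy must be 0 or 1")
        if self.payoffs["eff_utility"] < 0:
            raise ValueError("eff_utility must be >= 0")


@dataclass
class Branch:
    probability: float
    child: "Node"
    label: str = ""


@dataclass
class ChanceNode:
    """Chance node; branch order is part of the definition (seed-portable)."""

    branches: list[Branch]

    def probabilities(self) -> np.ndarray:
        return np.array([b.probability for b in self.branches])


Node = Union[TerminalNode, ChanceNode]


@dataclass
class DecisionTree:
    root: Node
    strategy_name: str = ""


@dataclass
class StrategyResult:
    """Expected payoffs and outcome-probability mass of one strategy."""

    strategy_name: str
    expected: dict[str, float]
    outcome_mass: dict[str, float]

    @property
    def cost(self) -> float:
        return self.expected["cost"]


@dataclass
class CEAComparison:
    """Incremental comparison of an alternative strategy vs a reference.

    ``dominance`` is ``alt_dominated`` (costs more, less effect),
    ``alt_dominant`` (costs less, more effect) or ``tradeoff_icer``.
    ``icer`` (delta cost / delta effect) is populated for trade-offs;
    ``cost_per_case_averted`` carries |dC/dE| whenever the alternative
    spends more to *reduce* the effect measure, which is the natural
    reading when the effect counts adverse events.
    """

    delta_cost: float
    delta_eff: float
    icer: float | None
    dominance: str
    cost_per_case_averted: float | None = None
    effect_key: str = ""


@dataclass
class MicrosimResult:
    """Empirical strategy result from path sampling, with standard errors."""

    strategy_name: str
    n: int
    expected: dict[str, float]
    se: dict[str, float]
    outcome_mass: dict[str, float]
    outcome_se: dict[str, float]


# ---------------------------------------------------------------------------


def validate_tree(t: DecisionTree) -> list[str]:
    """Structural validation; an empty report means the tree is sound."""
    report: list[str] = []

    def visit(node: Node, path: str) -> None:
        if isinstance(node, TerminalNode):
            return
        if isinstance(node, ChanceNode):
            if not node.branches:
                report.append(f"{path}: chance node with no branches")
                return
            probs = [b.probability for b in node.branches]
            if any(p < 0 or p > 1 for p in probs):
                report.append(f"{path}: branch probability outside [0,1]: {probs}")
            s = sum(probs)
            if abs(s - 1.0) > _PROB_TOL:
                report.append(f"{path}: sum={s!r}")
            for i, b in enumerate(node.branches):
                visit(b.child, f"{path}/{b.label or i}")
        else:
            report.append(f"{path}: unknown node type {type(node).__name__}")

    visit(t.root, t.strategy_name or "root")
    return report


def enumerate_paths(
    t: DecisionTree,
) -> Iterator[tuple[float, tuple[str, ...], TerminalNode]]:
    """Yield every root-to-leaf path as (probability, labels, terminal)."""

    def walk(node: Node, prob: float, labels: tuple[str, ...]):
        if isinstance(node, TerminalNode):
            yield prob, labels, node
        else:
            for b in node.branches:
                yield from walk(b.child, prob * b.probability, labels + (b.label,))

    yield from walk(t.root, 1.0, ())


def rollback(t: DecisionTree, key: str) -> float:
    """Expected value of one payoff key by depth-first rollback."""
    if key not in PAYOFF_KEYS:
        raise KeyError(f"unknown payoff key {key!r}; expected one of {PAYOFF_KEYS}")

    def value(node: Node) -> float:
        if isinstance(node, TerminalNode):
            return node.payoffs[key]
        return sum(b.probability * value(b.child) for b in node.branches)

    return value(t.root)


def strategy_result(t: DecisionTree) -> StrategyResult:
    """All payoff expectations plus outcome-label mass in a single pass."""
    expected = dict.fromkeys(PAYOFF_KEYS, 0.0)
    mass = dict.fromkeys(OUTCOME_LABELS, 0.0)
    for prob, _, leaf in enumerate_paths(t):
        for k in PAYOFF_KEYS:
            expected[k] += prob * leaf.payoffs[k]
        mass[leaf.outcome_label] += prob
    return StrategyResult(t.strategy_name, expected, mass)


def compare(
    reference: StrategyResult, alternative: StrategyResult, key: str
) -> CEAComparison:
    """Incremental cost-effectiveness of ``alternative`` vs ``reference``."""
    if key not in reference.expected or key not in alternative.expected:
        raise KeyError(f"payoff key {key!r} missing from a strategy result")
    d_cost = alternative.cost - reference.cost
    d_eff = alternative.expected[key] - reference.expected[key]

    icer: float | None = None
    per_averted: float | None = None
    if d_eff == 0:
        dominance = (
            "alt_dominated" if d_cost > 0 else "alt_dominant" if d_cost < 0 else "tradeoff_icer"
        )
    elif d_cost > 0 and d_eff < 0:
        dominance = "alt_dominated"
        per_averted = abs(d_cost / d_eff)
    elif d_cost < 0 and d_eff > 0:
        dominance = "alt_dominant"
    else:
        dominance = "tradeoff_icer"
        icer = d_cost / d_eff
    return CEAComparison(d_cost, d_eff, icer, dominance, per_averted, key)


def microsimulate(t: DecisionTree, n: int, seed: int) -> MicrosimResult:
    """Monte Carlo path-sampling estimate of the strategy result.

    Each of the ``n`` walkers descends the tree drawing one uniform variate
    per chance node (inverse CDF over the node's branch order), so results
    are reproducible for a fixed seed and tree definition.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    problems = validate_tree(t)
    if problems:
        raise ValueError("invalid tree: " + "; ".join(problems))

    leaves: list[TerminalNode] = []
    leaf_of_sample = np.empty(n, dtype=np.int64)
    rng = np.random.default_rng(seed)

    def descend(node: Node, idx: np.ndarray) -> None:
        if isinstance(node, TerminalNode):
            leaf_of_sample[idx] = len(leaves)
            leaves.append(node)
            return
        cum = np.cumsum(node.probabilities())
        cum[-1] = 1.0  # guard the open end against rounding
        u = rng.random(idx.size)
        choice = np.searchsorted(cum, u, side="right")
        for i, b in enumerate(node.branches):
            sub = idx[choice == i]
            if sub.size:
                descend(b.child, sub)

    descend(t.root, np.arange(n))

    expected: dict[str, float] = {}
    se: dict[str, float] = {}
    for k in PAYOFF_KEYS:
        vals = np.array([leaf.payoffs[k] for leaf in leaves])[leaf_of_sample]
        expected[k] = float(vals.mean())
        se[k] = float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    mass: dict[str, float] = {}
    mass_se: dict[str, float] = {}
    for label in OUTCOME_LABELS:
        ind = np.array([leaf.outcome_label == label for leaf in leaves])[leaf_of_sample]
        phat = float(ind.mean())
        mass[label] = phat
        mass_se[label] = math.sqrt(phat * (1 - phat) / n)
    return MicrosimResult(t.strategy_name, n, expected, se, mass, mass_se)


# ---------------------------------------------------------------------------
# JSON-compatible serialization


def _node_to_dict(node: Node) -> dict:
    if isinstance(node, TerminalNode):
        return {
            "kind": "terminal",
            "outcome": node.outcome_label,
            "payoffs": dict(node.payoffs),
        }
    return {
        "kind": "chance",
        "branches": [
            {
                "probability": b.probability,
                "label": b.label,
                "child": _node_to_dict(b.child),
            }
            for b in node.branches
        ],
    }


def _node_from_dict(d: dict) -> Node:
    if d["kind"] == "terminal":
        return TerminalNode(d["outcome"], dict(d["payoffs"]))
    if d["kind"] == "chance":
        return ChanceNode(
            [
                Branch(b["probability"], _node_from_dict(b["child"]), b.get("label", ""))
                for b in d["branches"]
            ]
        )
    raise ValueError(f"unknown node kind {d.get('kind')!r}")


def tree_to_dict(t: DecisionTree) -> dict:
    return {"strategy": t.strategy_name, "root": _node_to_dict(t.root)}


def tree_from_dict(d: dict) -> DecisionTree:
    return DecisionTree(_node_from_dict(d["root"]), d.get("strategy", ""))
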