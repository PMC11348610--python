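"""Two-arm diagnostic decision tree and expected-value rollback.

The tree starts at a decision node choosing between the fully manual and
the computer-vision strategy. Within each strategy, a chance node splits
the referred patient by true sensitization status (prevalence), and a
second chance node by test outcome (sensitivity if sensitized, specificity
otherwise), giving four terminal pathways per arm: TP, FN, FP, TN.

Terminal payoffs are hospital costs per tested patient. Every pathway
carries one test's cost; a false negative additionally triggers a repeat
referral costed as (further_tests - 1) extra tests — priced at the manual
per-test cost under the default retest strategy, or at the arm's own cost
under the same-arm alternative. False positives carry no downstream cost
from the hospital perspective.

The expected cost of a strategy is the probability-weighted sum of
terminal payoffs over its root-to-leaf pathways; the incremental cost is
EV(computer-vision) - EV(manual), so negative values favour the
computer-vision arm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

from .params import ModelInputs, RetestStrategy, ScenarioValues

__all__ = [
    "Node",
    "DecisionTree",
    "PathwayOutcome",
    "IncrementalResult",
    "ValidationReport",
    "validate_tree",
    "rollback",
    "build_spt_tree",
    "pathway_outcomes",
    "expected_incremental",
    "tree_to_json",
    "base_case_report",
]

MANUAL = "manual"
DSPT = "dspt"

PROB_TOL = 1e-9


@dataclass(frozen=True)
class Node:
    """Decision, chance or terminal node.

    Chance children are (branch probability, child) pairs; decision
    children are plain nodes (one per strategy); terminals carry a payoff
    in CHF and no children.
    """

    kind: str  # "decision" | "chance" | "terminal"
    label: str
    children: tuple = ()
    payoff: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("decision", "chance", "terminal"):
            raise ValueError(f"unknown node kind {self.kind!r}")


@dataclass(frozen=True)
class DecisionTree:
    root: Node

    @property
    def strategy_labels(self) -> tuple[str, ...]:
        return tuple(child.label for child in self.root.children)


@dataclass(frozen=True)
class PathwayOutcome:
    strategy: str
    classification: str  # TP | FN | FP | TN
    probability: float
    payoff: float


@dataclass(frozen=True)
class IncrementalResult:
    """Expected cost per arm (CHF/test) and their difference.

    ``incremental`` = ev_dspt - ev_manual (negative favours the
    computer-vision arm); ``savings`` = -incremental.
    """

    ev_manual: float
    ev_dspt: float

    @property
    def incremental(self) -> float:
        return self.ev_dspt - self.ev_manual

    @property
    def savings(self) -> float:
        return self.ev_manual - self.ev_dspt


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


def validate_tree(tree: DecisionTree) -> ValidationReport:
    """Structural checks: probability sums, child placement, payoffs."""
    report = ValidationReport()

    def visit(node: Node, at_root: bool) -> None:
        if node.kind == "decision":
            if not at_root:
                report.violations.append(f"decision node {node.label!r} below the root")
            if not node.children:
                report.violations.append(f"decision node {node.label!r} has no strategies")
            for child in node.children:
                visit(child, at_root=False)
        elif node.kind == "chance":
            if not node.children:
                report.violations.append(f"chance node {node.label!r} has no branches")
                return
            total = 0.0
            for prob, child in node.children:
                if not (0.0 <= prob <= 1.0):
                    report.violations.append(
                        f"chance node {node.label!r}: branch probability {prob} outside [0, 1]"
                    )
                total += prob
                visit(child, at_root=False)
            if abs(total - 1.0) > PROB_TOL:
                report.violations.append(
                    f"chance node {node.label!r}: branch probabilities sum to {total!r}"
                )
        else:  # terminal
            if node.children:
                report.violations.append(f"terminal {node.label!r} has children")
            if node.payoff is None or not math.isfinite(node.payoff):
                report.violations.append(f"terminal {node.label!r} has no finite payoff")
            elif node.payoff < 0:
                report.violations.append(f"terminal {node.label!r} has negative payoff")

    if tree.root.kind != "decision":
        report.violations.append("root is not a decision node")
    visit(tree.root, at_root=True)
    return report


def _walk_pathways(node: Node, prob: float) -> Iterator[tuple[float, Node]]:
    if node.kind == "terminal":
        yield prob, node
    elif node.kind == "chance":
        for p, child in node.children:
            yield from _walk_pathways(child, prob * p)
    else:
        raise ValueError("decision node encountered below a strategy root")


def rollback(tree: DecisionTree) -> dict[str, float]:
    """Expected payoff per strategy: sum over root-to-terminal pathways of
    (product of branch probabilities) x payoff."""
    report = validate_tree(tree)
    if not report.passed:
        raise ValueError("invalid tree: " + "; ".join(report.violations))
    out: dict[str, float] = {}
    for strategy in tree.root.children:
        out[strategy.label] = sum(p * leaf.payoff for p, leaf in _walk_pathways(strategy, 1.0))
    return out


def _as_values(inputs: ModelInputs | ScenarioValues) -> ScenarioValues:
    return inputs.values() if isinstance(inputs, ModelInputs) else inputs


def _arm_subtree(
    arm: str,
    prevalence: float,
    sensitivity: float,
    specificity: float,
    arm_cost: float,
    retest_cost: float,
    further_tests: float,
) -> Node:
    fn_payoff = arm_cost + (further_tests - 1.0) * retest_cost
    sensitized = Node(
        "chance",
        f"{arm}/sensitized",
        children=(
            (sensitivity, Node("terminal", f"{arm}/TP", payoff=arm_cost)),
            (1.0 - sensitivity, Node("terminal", f"{arm}/FN", payoff=fn_payoff)),
        ),
    )
    not_sensitized = Node(
        "chance",
        f"{arm}/not_sensitized",
        children=(
            (1.0 - specificity, Node("terminal", f"{arm}/FP", payoff=arm_cost)),
            (specificity, Node("terminal", f"{arm}/TN", payoff=arm_cost)),
        ),
    )
    return Node(
        "chance",
        arm,
        children=((prevalence, sensitized), (1.0 - prevalence, not_sensitized)),
    )


def build_spt_tree(inputs: ModelInputs | ScenarioValues) -> DecisionTree:
    """Build the two-strategy tree from a parameter set or a numeric scenario."""
    v = _as_values(inputs)
    if v.retest_strategy is RetestStrategy.MANUAL_RETEST:
        manual_retest_cost = v.manual_cost
        dspt_retest_cost = v.manual_cost
    else:
        manual_retest_cost = v.manual_cost
        dspt_retest_cost = v.dspt_cost
    manual = _arm_subtree(
        MANUAL,
        v.prevalence,
        v.manual_sensitivity,
        v.manual_specificity,
        v.manual_cost,
        manual_retest_cost,
        v.further_tests,
    )
    dspt = _arm_subtree(
        DSPT,
        v.prevalence,
        v.dspt_sensitivity,
        v.dspt_specificity,
        v.dspt_cost,
        dspt_retest_cost,
        v.further_tests,
    )
    return DecisionTree(root=Node("decision", "spt_strategy", children=(manual, dspt)))


def pathway_outcomes(inputs: ModelInputs | ScenarioValues) -> list[PathwayOutcome]:
    """Flattened TP/FN/FP/TN pathway probabilities and payoffs per strategy."""
    tree = build_spt_tree(inputs)
    outcomes = []
    for strategy in tree.root.children:
        for prob, leaf in _walk_pathways(strategy, 1.0):
            outcomes.append(
                PathwayOutcome(
                    strategy=strategy.label,
                    classification=leaf.label.rsplit("/", 1)[-1],
                    probability=prob,
                    payoff=leaf.payoff,
                )
            )
    return outcomes


def expected_incremental(inputs: ModelInputs | ScenarioValues) -> IncrementalResult:
    """Roll back both arms and return expected costs and their difference."""
    evs = rollback(build_spt_tree(inputs))
    return IncrementalResult(ev_manual=evs[MANUAL], ev_dspt=evs[DSPT])


def _node_to_dict(node: Node, probability: float | None = None) -> dict:
    d: dict = {"kind": node.kind, "label": node.label}
    if probability is not None:
        d["probability"] = probability
    if node.kind == "terminal":
        d["payoff"] = node.payoff
    elif node.kind == "chance":
        d["children"] = [_node_to_dict(child, p) for p, child in node.children]
    else:
        d["children"] = [_node_to_dict(child) for child in node.children]
    return d


def tree_to_json(tree: DecisionTree, path: str | Path | None = None) -> str:
    """Serialize the tree (kind, label, probability, payoff, children)."""
    text = json.dumps(_node_to_dict(tree.root), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def base_case_report(inputs: ModelInputs | ScenarioValues) -> pd.DataFrame:
    """One row per strategy plus an incremental row, costs in CHF per test."""
    res = expected_incremental(inputs)
    return pd.DataFrame(
        {
            "strategy": ["manual", "dspt", "incremental (dspt - manual)"],
            "expected_cost_chf_per_test": [res.ev_manual, res.ev_dspt, res.incremental],
        }
    )
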