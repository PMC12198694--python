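"""Per-arm decision tree and expected-value rollback.

Each referred patient enters at a polyclinic (NUP) visit and is referred to a
specialist outpatient clinic (SOC).  The chance structure, identical in both
arms but with arm-specific probabilities and prices, is:

    wait stratum (<20 days / >=20 days)
      -> attends the specialist appointment?
           yes -> duplicate tests? -> admitted after the SOC visit?
           no  -> ED visit with admission, or remains healthy

which yields 12 terminal paths per arm.  Terminal costs accumulate the NUP
visit, the SOC visit (with- or without-duplicate price), and admission and ED
costs where incurred; the one-year utility is the admitted utility on any path
with an admission and the nonadmitted utility otherwise.

``rollback`` computes expected cost, expected QALYs and the overall admission
probability by leaf-to-root recursion; ``enumerate_paths`` is the exhaustive
path-sum oracle the rollback must agree with exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

from .parameters import ARMS, SHARED, ParameterError, ParameterTable

_PROB_TOL = 1e-12

__all__ = [
    "TerminalNode",
    "ChanceNode",
    "DecisionTree",
    "PathOutcome",
    "ArmOutcome",
    "build_arm_tree",
    "tree_from_values",
    "rollback",
    "enumerate_paths",
    "admission_relative_reduction",
]


@dataclass(frozen=True)
class TerminalNode:
    """A leaf: total path cost (S$), one-year utility, and admission status."""

    label: str
    cost: float
    utility: float
    admitted: bool = False

    def __post_init__(self) -> None:
        if self.cost < 0.0:
            raise ValueError(f"{self.label}: terminal cost must be nonnegative")
        if not 0.0 <= self.utility <= 1.0:
            raise ValueError(f"{self.label}: utility must lie in [0, 1]")


@dataclass(frozen=True)
class ChanceNode:
    label: str
    branches: tuple[tuple[float, Union["ChanceNode", TerminalNode]], ...]

    def __post_init__(self) -> None:
        total = 0.0
        for prob, _ in self.branches:
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{self.label}: branch probability {prob} outside [0, 1]")
            total += prob
        if abs(total - 1.0) > _PROB_TOL:
            raise ValueError(f"{self.label}: branch probabilities sum to {total}, not 1")


Node = Union[ChanceNode, TerminalNode]


@dataclass(frozen=True)
class DecisionTree:
    arm: str
    root: ChanceNode

    def to_dict(self) -> dict:
        def convert(node: Node) -> dict:
            if isinstance(node, TerminalNode):
                return {
                    "label": node.label,
                    "cost": node.cost,
                    "utility": node.utility,
                    "admitted": node.admitted,
                }
            return {
                "label": node.label,
                "branches": [
                    {"probability": p, "node": convert(child)} for p, child in node.branches
                ],
            }

        return {"arm": self.arm, "root": convert(self.root)}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass(frozen=True)
class PathOutcome:
    path: tuple[str, ...]
    probability: float
    cost: float
    utility: float
    admitted: bool


@dataclass(frozen=True)
class ArmOutcome:
    expected_cost: float
    expected_qalys: float
    admission_probability: float


def _lookup(values: Mapping[tuple[str, str], float], name: str, arm: str) -> float:
    if (name, arm) in values:
        return values[(name, arm)]
    if (name, SHARED) in values:
        return values[(name, SHARED)]
    raise ParameterError(f"missing parameter {name!r} for arm {arm!r}")


def tree_from_values(values: Mapping[tuple[str, str], float], arm: str) -> DecisionTree:
    """Build the arm's tree from a plain (name, arm) -> value mapping.

    This is the single tree constructor used for the base case, PSA draws and
    one-way substitutions alike; shared parameters resolve through the
    ``(name, "shared")`` key.
    """
    if arm not in ARMS:
        raise ParameterError(f"unknown arm {arm!r}")

    def v(name: str) -> float:
        return _lookup(values, name, arm)

    c_nup = v("c_nup_visit")
    c_soc = v("c_soc_visit")
    c_soc_dup = v("c_soc_visit_duplicate")
    c_adm = v("c_admission")
    c_ed = v("c_ed_visit")
    u_adm = v("u_admitted")
    u_non = v("u_nonadmitted")
    p_adm = v("p_admission")
    p_ed = v("p_ed_admission")
    p_dup = v("p_duplicate")

    def admission_split(label: str, visit_cost: float) -> ChanceNode:
        return ChanceNode(
            label,
            (
                (
                    p_adm,
                    TerminalNode("admitted", c_nup + visit_cost + c_adm, u_adm, admitted=True),
                ),
                (1.0 - p_adm, TerminalNode("not admitted", c_nup + visit_cost, u_non)),
            ),
        )

    def stratum(label: str, p_attend: float) -> ChanceNode:
        specialist = ChanceNode(
            "specialist",
            (
                (p_dup, admission_split("duplicate tests", c_soc_dup)),
                (1.0 - p_dup, admission_split("no duplicate tests", c_soc)),
            ),
        )
        no_specialist = ChanceNode(
            "no specialist",
            (
                (
                    p_ed,
                    TerminalNode(
                        "ED visit and admission", c_nup + c_ed + c_adm, u_adm, admitted=True
                    ),
                ),
                (1.0 - p_ed, TerminalNode("healthy", c_nup, u_non)),
            ),
        )
        return ChanceNode(label, ((p_attend, specialist), (1.0 - p_attend, no_specialist)))

    p_lt20 = v("p_wait_lt20")
    root = ChanceNode(
        "referral",
        (
            (p_lt20, stratum("wait<20 days", v("p_attend_lt20"))),
            (1.0 - p_lt20, stratum("wait>=20 days", v("p_attend_ge20"))),
        ),
    )
    return DecisionTree(arm=arm, root=root)


def build_arm_tree(
    params: ParameterTable,
    arm: str,
    overrides: Mapping[tuple[str, str], float] | None = None,
) -> DecisionTree:
    """Build one arm's tree at the base-case means, optionally overriding
    individual ``(name, arm)`` values (one-way sensitivity analyses)."""
    values = params.base_case_mapping()
    if overrides:
        values.update(overrides)
    return tree_from_values(values, arm)


def rollback(tree: DecisionTree) -> ArmOutcome:
    """Expected cost, expected QALYs and admission probability by recursion."""

    def roll(node: Node) -> tuple[float, float, float]:
        if isinstance(node, TerminalNode):
            return node.cost, node.utility, 1.0 if node.admitted else 0.0
        cost = qalys = admitted = 0.0
        for prob, child in node.branches:
            c, q, a = roll(child)
            cost += prob * c
            qalys += prob * q
            admitted += prob * a
        return cost, qalys, admitted

    cost, qalys, admitted = roll(tree.root)
    return ArmOutcome(cost, qalys, admitted)


def enumerate_paths(tree: DecisionTree) -> list[PathOutcome]:
    """Exhaustive root-to-leaf path list (the rollback oracle)."""
    paths: list[PathOutcome] = []

    def walk(node: Node, labels: tuple[str, ...], prob: float) -> None:
        if isinstance(node, TerminalNode):
            paths.append(
                PathOutcome(labels + (node.label,), prob, node.cost, node.utility, node.admitted)
            )
            return
        for p, child in node.branches:
            child_labels = labels + (child.label,) if isinstance(child, ChanceNode) else labels
            walk(child, child_labels, prob * p)

    walk(tree.root, (), 1.0)
    return paths


def admission_relative_reduction(emr: ArmOutcome, ngemr: ArmOutcome) -> float:
    """Percent relative reduction in the modeled overall admission rate."""
    if emr.admission_probability <= 0.0:
        raise ValueError("relative reduction undefined: comparator admission probability is 0")
    return (
        100.0
        * (emr.admission_probability - ngemr.admission_probability)
        / emr.admission_probability
    )
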