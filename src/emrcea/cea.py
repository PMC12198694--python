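"""Incremental cost-effectiveness mathematics.

Given the rolled-back outcomes of the comparator (legacy EMR) and intervention
(NGEMR) arms, this module computes the incremental cost ΔC, incremental
effectiveness ΔE (QALYs), the ICER ΔC/ΔE, net monetary benefit λ·E − C at a
willingness-to-pay λ, and the dominance class of the (ΔC, ΔE) quadrant.
Willingness-to-pay thresholds are expressed as multiples of GDP per capita
(2021 Singapore: S$97,798, with 0.5× = S$48,899 the reference threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .tree import ArmOutcome

#: Display-only conversion used in reports; all computation is in 2021 S$.
SGD_PER_USD = 1.35

#: 2021 GDP per capita (S$) anchoring the willingness-to-pay thresholds.
GDP_PER_CAPITA_2021 = 97798.0

DOMINANT = "intervention dominant"
DOMINATED = "intervention dominated"
TRADEOFF_NE = "trade-off NE"
TRADEOFF_SW = "trade-off SW"
TIE = "tie"

__all__ = [
    "SGD_PER_USD",
    "GDP_PER_CAPITA_2021",
    "DOMINANT",
    "DOMINATED",
    "TRADEOFF_NE",
    "TRADEOFF_SW",
    "TIE",
    "WtpConfig",
    "IncrementalResult",
    "incremental",
    "nmb",
    "incremental_nmb",
    "wtp_from_gdp",
    "table2_frame",
]


@dataclass(frozen=True)
class WtpConfig:
    """Willingness-to-pay configuration: GDP anchor and threshold list (S$/QALY)."""

    gdp_per_capita: float = GDP_PER_CAPITA_2021
    thresholds: tuple[float, ...] = (GDP_PER_CAPITA_2021 * 0.5, GDP_PER_CAPITA_2021)

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.thresholds):
            raise ValueError("WTP thresholds must be positive")
        if list(self.thresholds) != sorted(self.thresholds):
            raise ValueError("WTP thresholds must be sorted ascending")


@dataclass(frozen=True)
class IncrementalResult:
    delta_cost: float
    delta_qalys: float
    icer: float | None
    dominance: str


def incremental(comparator: ArmOutcome, intervention: ArmOutcome) -> IncrementalResult:
    """Incremental result of intervention vs comparator.

    The ICER is undefined (``None``) when ΔE = 0; ties classify as weak
    dominance toward the cheaper or more effective arm, and exact equality of
    both increments is a tie.
    """
    for out in (comparator, intervention):
        if not (math.isfinite(out.expected_cost) and math.isfinite(out.expected_qalys)):
            raise ValueError("arm outcomes must be finite")
    d_cost = intervention.expected_cost - comparator.expected_cost
    d_qalys = intervention.expected_qalys - comparator.expected_qalys
    icer = d_cost / d_qalys if d_qalys != 0.0 else None
    if d_cost == 0.0 and d_qalys == 0.0:
        dominance = TIE
    elif d_qalys >= 0.0 and d_cost <= 0.0:
        dominance = DOMINANT
    elif d_qalys <= 0.0 and d_cost >= 0.0:
        dominance = DOMINATED
    elif d_qalys > 0.0:
        dominance = TRADEOFF_NE
    else:
        dominance = TRADEOFF_SW
    return IncrementalResult(d_cost, d_qalys, icer, dominance)


def nmb(outcome: ArmOutcome, wtp: float) -> float:
    """Net monetary benefit λ·QALYs − cost (S$)."""
    if wtp < 0.0:
        raise ValueError("willingness-to-pay must be nonnegative")
    return wtp * outcome.expected_qalys - outcome.expected_cost


def incremental_nmb(comparator: ArmOutcome, intervention: ArmOutcome, wtp: float) -> float:
    """λ·ΔE − ΔC; positive iff the intervention is cost-effective at λ."""
    return nmb(intervention, wtp) - nmb(comparator, wtp)


def wtp_from_gdp(gdp_per_capita: float, multiplier: float) -> float:
    """WTP threshold as a multiple of GDP per capita (S$/QALY)."""
    if gdp_per_capita <= 0.0 or multiplier < 0.0:
        raise ValueError("GDP per capita must be positive and multiplier nonnegative")
    return gdp_per_capita * multiplier


def table2_frame(comparator: ArmOutcome, intervention: ArmOutcome) -> pd.DataFrame:
    """Base-case report: costs, QALYs, increments and ICER for both arms.

    Values are unrounded; the US$ columns are a fixed-rate display transform.
    """
    inc = incremental(comparator, intervention)
    if inc.icer is None:
        icer_text = f"undefined (dominance: {inc.dominance})"
    else:
        icer_text = inc.icer
    rows = [
        ("Costs (S$)", comparator.expected_cost, intervention.expected_cost),
        ("QALYs", comparator.expected_qalys, intervention.expected_qalys),
        ("Incremental costs (S$)", None, inc.delta_cost),
        ("Incremental QALYs", None, inc.delta_qalys),
        ("ICER (S$ per QALY)", None, icer_text),
    ]
    frame = pd.DataFrame(rows, columns=["indicator", "comparator", "intervention"])

    def usd(value):
        return value / SGD_PER_USD if isinstance(value, (int, float)) and value is not None else None

    frame["comparator_usd"] = [
        usd(v) if "S$" in ind else None for ind, v in zip(frame["indicator"], frame["comparator"])
    ]
    frame["intervention_usd"] = [
        usd(v) if "S$" in ind else None
        for ind, v in zip(frame["indicator"], frame["intervention"])
    ]
    return frame
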