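"""Uncertainty analyses around the base-case decision tree.

* Probabilistic sensitivity analysis (PSA): repeated rollback of both arms
  with every non-fixed parameter drawn independently from its moment-matched
  (or explicitly parameterised) distribution; one shared random stream with
  the table's canonical parameter order makes runs bit-reproducible per seed.
* Cost-effectiveness acceptability curve (CEAC): fraction of PSA draws with
  positive incremental net monetary benefit across a WTP grid.
* One-way (tornado) sensitivity analysis: each non-fixed parameter swung to
  its 95% CI bounds (IQR bounds where only an explicit shape/scale is known,
  i.e. the admission cost), others held at base case; entries ranked by the
  width of the incremental-NMB range at a reference WTP.  Per-arm entries of
  a background quantity with an assumed intervention effect (the admission
  rate) shift together rather than independently.  The per-bound ICERs
  are reported but not used for ranking, because ΔE may change sign inside a
  bound pair and send the ICER through ±infinity.
* Threshold (breakeven) search: bisection on a criterion that is affine in
  any single parameter (ΔC for cost saving, ΔC − λ·ΔE for ICER ≤ λ), with a
  closed-form affine solve available as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cea
from .parameters import (
    ParameterTable,
    beta_from_mean_se,
    ci95,
    gamma_from_mean_se,
    iqr_bounds,
)
from .tree import ArmOutcome, rollback, tree_from_values

__all__ = [
    "PsaConfig",
    "PsaResult",
    "CeacPoint",
    "TornadoEntry",
    "ThresholdResult",
    "NoRootError",
    "sample_parameters",
    "run_psa",
    "prob_cost_effective",
    "ceac",
    "one_way_tornado",
    "threshold_search",
    "threshold_closed_form",
    "write_psa_csv",
    "write_ceac_csv",
    "write_tornado_csv",
    "write_thresholds_csv",
]

DEFAULT_WTP_GRID: tuple[float, ...] = tuple(float(w) for w in range(0, 150001, 1000))

DRAW_COLUMNS = (
    "emr_cost",
    "emr_qalys",
    "ngemr_cost",
    "ngemr_qalys",
    "delta_cost",
    "delta_qalys",
)


class NoRootError(RuntimeError):
    """The threshold criterion does not change sign over the search interval."""


#: Parameters whose per-arm entries describe the same background quantity
#: (the post-specialist admission rate of the served population), with the
#: arm difference a structural intervention assumption rather than two
#: independent uncertainties.  One-way swings shift both arms' values by the
#: same amount, preserving the assumed effect; swinging them independently
#: would let a background-level shift masquerade as the dominant driver of
#: the incremental result.
LEVEL_SHIFT_NAMES: tuple[str, ...] = ("p_admission",)


@dataclass(frozen=True)
class PsaConfig:
    seed: int
    n_draws: int = 1000
    wtp_grid: tuple[float, ...] = DEFAULT_WTP_GRID

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        grid = list(self.wtp_grid)
        if any(w < 0 for w in grid) or grid != sorted(grid):
            raise ValueError("wtp_grid must be nonnegative and ascending")


@dataclass(frozen=True)
class PsaResult:
    """Per-draw arm outcomes and increments, with the parameter realizations."""

    draws: pd.DataFrame
    realizations: pd.DataFrame
    seed: int
    table_sha256: str


@dataclass(frozen=True)
class CeacPoint:
    wtp: float
    probability_cost_effective: float


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    arm: str
    bound_low: float
    bound_high: float
    icer_low: float
    icer_high: float
    nmb_range: float
    cost_saving: bool


@dataclass(frozen=True)
class ThresholdResult:
    name: str
    arm: str
    criterion: str
    value: float
    interval: tuple[float, float]
    residual: float


def sample_parameters(
    table: ParameterTable, rng: np.random.Generator
) -> dict[tuple[str, str], float]:
    """One joint draw: independent sampling per non-fixed parameter, in the
    table's canonical order; fixed parameters pass through at base case."""
    values: dict[tuple[str, str], float] = {}
    for spec in table:
        if spec.family == "fixed":
            values[spec.key] = spec.mean
        elif spec.family == "beta":
            a, b = beta_from_mean_se(spec.mean, spec.se)
            values[spec.key] = float(rng.beta(a, b))
        else:
            if spec.shape is not None and spec.scale is not None:
                shape, scale = spec.shape, spec.scale
            else:
                shape, scale = gamma_from_mean_se(spec.mean, spec.se)
            values[spec.key] = float(rng.gamma(shape, scale))
    return values


def _arm_outcomes(values) -> tuple[ArmOutcome, ArmOutcome]:
    return (
        rollback(tree_from_values(values, "EMR")),
        rollback(tree_from_values(values, "NGEMR")),
    )


def run_psa(table: ParameterTable, config: PsaConfig) -> PsaResult:
    """Monte Carlo PSA: rebuild and roll back both arms per joint draw."""
    rng = np.random.default_rng(config.seed)
    rows = np.empty((config.n_draws, len(DRAW_COLUMNS)))
    realizations = []
    for i in range(config.n_draws):
        values = sample_parameters(table, rng)
        emr, ngemr = _arm_outcomes(values)
        rows[i] = (
            emr.expected_cost,
            emr.expected_qalys,
            ngemr.expected_cost,
            ngemr.expected_qalys,
            ngemr.expected_cost - emr.expected_cost,
            ngemr.expected_qalys - emr.expected_qalys,
        )
        realizations.append({f"{name}@{arm}": v for (name, arm), v in values.items()})
    return PsaResult(
        draws=pd.DataFrame(rows, columns=list(DRAW_COLUMNS)),
        realizations=pd.DataFrame(realizations),
        seed=config.seed,
        table_sha256=table.sha256(),
    )


def prob_cost_effective(psa: PsaResult, wtp: float) -> float:
    """Fraction of draws with strictly positive incremental NMB at ``wtp``."""
    if len(psa.draws) == 0:
        raise ValueError("empty PSA result")
    gain = wtp * psa.draws["delta_qalys"].to_numpy() - psa.draws["delta_cost"].to_numpy()
    return float(np.mean(gain > 0.0))


def ceac(psa: PsaResult, grid: tuple[float, ...] | None = None) -> list[CeacPoint]:
    """Acceptability curve over a WTP grid, same draws throughout."""
    if grid is None:
        grid = DEFAULT_WTP_GRID
    if list(grid) != sorted(grid):
        raise ValueError("WTP grid must be ascending")
    return [CeacPoint(float(w), prob_cost_effective(psa, w)) for w in grid]


def _sensitivity_bounds(spec) -> tuple[float, float]:
    # IQR bounds where only an explicit shape/scale (no SE) is available.
    if spec.se is None and spec.shape is not None:
        return iqr_bounds(spec)
    return ci95(spec)


def one_way_tornado(
    table: ParameterTable, reference_wtp: float = cea.GDP_PER_CAPITA_2021 * 0.5
) -> list[TornadoEntry]:
    """One-way swing of every non-fixed parameter between its bounds.

    Shared parameters are substituted in both arms simultaneously.  Entries
    are sorted descending by incremental-NMB range width at ``reference_wtp``.
    """
    base = table.base_case_mapping()
    entries = []
    for spec in table:
        if spec.family == "fixed":
            continue
        low, high = _sensitivity_bounds(spec)
        results = []
        for bound in (low, high):
            values = dict(base)
            values[spec.key] = bound
            if spec.name in LEVEL_SHIFT_NAMES:
                delta = bound - spec.mean
                for other in table:
                    if other.name == spec.name and other.key != spec.key:
                        values[other.key] = other.mean + delta
            emr, ngemr = _arm_outcomes(values)
            results.append(cea.incremental(emr, ngemr))
        gains = [reference_wtp * r.delta_qalys - r.delta_cost for r in results]
        entries.append(
            TornadoEntry(
                name=spec.name,
                arm=spec.arm,
                bound_low=low,
                bound_high=high,
                icer_low=results[0].icer if results[0].icer is not None else math.nan,
                icer_high=results[1].icer if results[1].icer is not None else math.nan,
                nmb_range=abs(gains[1] - gains[0]),
                cost_saving=any(r.delta_cost < 0.0 for r in results),
            )
        )
    entries.sort(key=lambda e: e.nmb_range, reverse=True)
    return entries


def _criterion_function(table, name, arm, criterion, wtp):
    base = table.base_case_mapping()
    key = (name, table.get(name, arm).arm)  # resolve shared entries

    def f(x: float) -> float:
        values = dict(base)
        values[key] = x
        emr, ngemr = _arm_outcomes(values)
        inc = cea.incremental(emr, ngemr)
        if criterion == "cost_saving":
            return inc.delta_cost
        if criterion == "icer_le":
            if wtp is None:
                raise ValueError("criterion 'icer_le' needs a WTP threshold")
            # ΔC − λΔE: affine in x, zero exactly where ICER = λ (given ΔE > 0)
            return inc.delta_cost - wtp * inc.delta_qalys
        raise ValueError(f"unknown criterion {criterion!r}")

    return f


def threshold_search(
    table: ParameterTable,
    name: str,
    arm: str,
    criterion: str,
    interval: tuple[float, float],
    wtp: float | None = None,
    tol: float = 1e-6,
) -> ThresholdResult:
    """Bisection breakeven search for one parameter, others at base case.

    ``criterion`` is ``"cost_saving"`` (root of ΔC) or ``"icer_le"`` (root of
    ΔC − λ·ΔE).  Raises :class:`NoRootError` if the criterion does not change
    sign over ``interval``; never clamps silently.
    """
    lo, hi = float(interval[0]), float(interval[1])
    if not lo < hi:
        raise ValueError("interval must satisfy lo < hi")
    f = _criterion_function(table, name, arm, criterion, wtp)
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == 0.0 and f_hi == 0.0:
        raise NoRootError(
            f"{criterion} criterion is identically zero in {name!r} on [{lo}, {hi}] "
            "(the arms are indistinguishable)"
        )
    if f_lo == 0.0:
        return ThresholdResult(name, arm, criterion, lo, (lo, hi), 0.0)
    if f_hi == 0.0:
        return ThresholdResult(name, arm, criterion, hi, (lo, hi), 0.0)
    if math.copysign(1.0, f_lo) == math.copysign(1.0, f_hi):
        raise NoRootError(
            f"{criterion} criterion for {name!r} does not change sign on "
            f"[{lo}, {hi}] (f={f_lo:.6g} .. {f_hi:.6g})"
        )
    a, b, f_a = lo, hi, f_lo
    for _ in range(200):
        mid = 0.5 * (a + b)
        f_mid = f(mid)
        if math.copysign(1.0, f_mid) == math.copysign(1.0, f_a):
            a, f_a = mid, f_mid
        else:
            b = mid
        if b - a <= 1e-13 * max(1.0, abs(lo), abs(hi)):
            break
    root = 0.5 * (a + b)
    residual = f(root)
    if abs(residual) > tol:
        raise NoRootError(
            f"bisection residual {residual:.3g} exceeds tolerance {tol} for {name!r}"
        )
    return ThresholdResult(name, arm, criterion, root, (lo, hi), residual)


def threshold_closed_form(
    table: ParameterTable,
    name: str,
    arm: str,
    criterion: str,
    interval: tuple[float, float],
    wtp: float | None = None,
) -> float:
    """Exact breakeven via the affine structure: the criterion is linear in any
    single probability or cost parameter, so two endpoint evaluations give the
    root by linear interpolation.  Used as an independent check on bisection."""
    lo, hi = float(interval[0]), float(interval[1])
    f = _criterion_function(table, name, arm, criterion, wtp)
    f_lo, f_hi = f(lo), f(hi)
    if f_lo == f_hi:
        raise NoRootError(f"criterion is constant in {name!r} on [{lo}, {hi}]")
    root = lo - f_lo * (hi - lo) / (f_hi - f_lo)
    if not lo <= root <= hi:
        raise NoRootError(f"closed-form root {root} falls outside [{lo}, {hi}]")
    return root


def _write_csv(frame: pd.DataFrame, path: str | Path, header_fields: dict) -> None:
    path = Path(path)
    header = "# " + " ".join(f"{k}={v}" for k, v in header_fields.items())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        frame.to_csv(fh, index=False)


def write_psa_csv(psa: PsaResult, path: str | Path) -> None:
    frame = pd.concat([psa.draws, psa.realizations], axis=1)
    _write_csv(frame, path, {"seed": psa.seed, "table_sha256": psa.table_sha256})


def write_ceac_csv(
    points: list[CeacPoint], path: str | Path, seed: int, table_sha256: str
) -> None:
    frame = pd.DataFrame(
        [(p.wtp, p.probability_cost_effective) for p in points],
        columns=["wtp", "probability_cost_effective"],
    )
    _write_csv(frame, path, {"seed": seed, "table_sha256": table_sha256})


def write_tornado_csv(entries: list[TornadoEntry], path: str | Path, table_sha256: str) -> None:
    frame = pd.DataFrame([vars(e) for e in entries])
    _write_csv(frame, path, {"table_sha256": table_sha256})


def write_thresholds_csv(
    results: list[ThresholdResult], path: str | Path, table_sha256: str
) -> None:
    frame = pd.DataFrame(
        [
            {
                "name": r.name,
                "arm": r.arm,
                "criterion": r.criterion,
                "value": r.value,
                "interval_lo": r.interval[0],
                "interval_hi": r.interval[1],
                "residual": r.residual,
            }
            for r in results
        ]
    )
    _write_csv(frame, path, {"table_sha256": table_sha256})
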