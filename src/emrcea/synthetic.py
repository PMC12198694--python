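"""Synthetic polyclinic (NUP) and specialist-clinic (SOC) billing extracts.

The real study parameterised its decision tree from two unlinked visit-level
extracts: polyclinic bills and specialist-outpatient-clinic referrals across a
pre-period (legacy EMR) and a post-period (integrated NGEMR).  This module
generates visit records with the same statistical structure and re-estimates
the data-derived model parameters from them:

* SOC waiting times follow a per-period gamma distribution whose scale is
  solved so that P(wait < 20 days) hits the period's target proportion at a
  fixed coefficient of variation (the real waiting-time law is unpublished;
  only the sub-20-day proportions are).  Days are integer; "< 20 days" is
  strict, i.e. wait_days <= 19.
* Attendance is Bernoulli conditional on the wait stratum, duplicate testing
  Bernoulli among attendees, and bills per-visit gamma by setting, period and
  visit type (acute/chronic).  SOC bills of duplicate-test visits carry the
  assumed duplicate surcharge, so the "without duplicate tests" visit cost is
  estimated from duplicate-free attended visits.
* The acute:chronic case mix shifts between periods; cost estimation
  reweights post-period strata to the pre-period mix (exact stratified
  reweighting on visit type — the one matching variable available), which
  removes the case-mix confounding by construction.

Cohorts are plain pandas DataFrames with the :class:`VisitRecord` columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import (
    LITERATURE_KEYS,
    DistributionSpec,
    ParameterTable,
    default_parameters,
)

SETTINGS = ("NUP", "SOC")
PERIODS = ("pre", "post")
PERIOD_TO_ARM = {"pre": "EMR", "post": "NGEMR"}
VISIT_TYPES = ("acute", "chronic")
WAIT_CUTOFF_DAYS = 20.0

COHORT_COLUMNS = (
    "patient_id",
    "setting",
    "period",
    "visit_type",
    "wait_days",
    "attended",
    "duplicate_test",
    "bill",
)

__all__ = [
    "SETTINGS",
    "PERIODS",
    "PERIOD_TO_ARM",
    "WAIT_CUTOFF_DAYS",
    "VisitRecord",
    "GeneratorConfig",
    "GenerationError",
    "EstimationError",
    "MatchingError",
    "waiting_gamma_params",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "estimate_waiting_proportion",
    "estimate_attendance",
    "estimate_costs_matched",
    "parameters_from_cohort",
]


class GenerationError(ValueError):
    """Invalid generator configuration."""


class EstimationError(ValueError):
    """A parameter cannot be estimated from the given records."""


class MatchingError(EstimationError):
    """Visit-type matching impossible (a stratum is missing in one period)."""


@dataclass(frozen=True)
class VisitRecord:
    """One synthetic visit.  SOC-only fields stay ``None`` on NUP records."""

    patient_id: str
    setting: str
    period: str
    visit_type: str
    bill: float
    wait_days: int | None = None
    attended: bool | None = None
    duplicate_test: bool | None = None

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")
        if self.visit_type not in VISIT_TYPES:
            raise ValueError(f"unknown visit type {self.visit_type!r}")
        if self.bill < 0.0:
            raise ValueError("bill must be nonnegative")
        if self.setting == "NUP":
            if self.wait_days is not None or self.attended is not None or self.duplicate_test is not None:
                raise ValueError("NUP records carry no SOC-only fields")
        else:
            if self.wait_days is None or self.wait_days < 0:
                raise ValueError("SOC records need a nonnegative wait_days")
            if self.attended is None:
                raise ValueError("SOC records need an attendance flag")
            if not self.attended and self.duplicate_test is not None:
                raise ValueError("duplicate_test is undefined for non-attended visits")


def _default_bill_means() -> dict[tuple[str, str, str], float]:
    # Acute visits are priced at 0.75x and chronic at 1.25x the period's
    # published mean visit cost, so a 50:50 pre-period mix reproduces it.
    published = {("NUP", "pre"): 102.30, ("NUP", "post"): 114.73,
                 ("SOC", "pre"): 189.07, ("SOC", "post"): 191.67}
    out = {}
    for (setting, period), mean in published.items():
        out[(setting, period, "acute")] = 0.75 * mean
        out[(setting, period, "chronic")] = 1.25 * mean
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """True data-generating process for the synthetic extracts.

    Defaults reproduce the published base-case parameters: sub-20-day waiting
    proportions 0.37 (pre) / 0.455 (post), attendance 0.866/0.82 (pre, by wait
    stratum) and 0.88/0.80 (post), duplicate-test probabilities 0.294/0.207,
    and mean visit costs 102.30/114.73 S$ (NUP) and 189.07/191.67 S$ (SOC,
    without duplicates) under the pre-period 50:50 acute:chronic mix.
    """

    seed: int
    n_patients: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: {(s, p): 15000 for s in SETTINGS for p in PERIODS}
    )
    p_wait_lt20: Mapping[str, float] = field(
        default_factory=lambda: {"pre": 0.37, "post": 0.455}
    )
    wait_cv: float = 0.75
    attendance: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("pre", "lt20"): 0.866,
            ("pre", "ge20"): 0.82,
            ("post", "lt20"): 0.88,
            ("post", "ge20"): 0.80,
        }
    )
    p_duplicate: Mapping[str, float] = field(
        default_factory=lambda: {"pre": 0.294, "post": 0.207}
    )
    bill_means: Mapping[tuple[str, str, str], float] = field(
        default_factory=_default_bill_means
    )
    bill_cv: float = 0.5
    duplicate_surcharge: Mapping[str, float] = field(
        default_factory=lambda: {"pre": 76.97, "post": 78.74}
    )
    acute_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"pre": 0.50, "post": 0.65}
    )

    def validate(self) -> None:
        for key, n in self.n_patients.items():
            if n < 0:
                raise GenerationError(f"negative cohort size for {key}")
        probs = (
            list(self.p_wait_lt20.values())
            + list(self.attendance.values())
            + list(self.p_duplicate.values())
            + list(self.acute_fraction.values())
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise GenerationError("probabilities must lie in [0, 1]")
        if self.wait_cv <= 0.0 or self.bill_cv <= 0.0:
            raise GenerationError("coefficients of variation must be positive")
        if any(m <= 0.0 for m in self.bill_means.values()):
            raise GenerationError("bill means must be positive")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "seed": self.seed,
            "n_patients": {f"{s}/{p}": n for (s, p), n in self.n_patients.items()},
            "p_wait_lt20": dict(self.p_wait_lt20),
            "wait_cv": self.wait_cv,
            "attendance": {f"{p}/{s}": v for (p, s), v in self.attendance.items()},
            "p_duplicate": dict(self.p_duplicate),
            "bill_means": {f"{s}/{p}/{t}": m for (s, p, t), m in self.bill_means.items()},
            "bill_cv": self.bill_cv,
            "duplicate_surcharge": dict(self.duplicate_surcharge),
            "acute_fraction": dict(self.acute_fraction),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def waiting_gamma_params(p_lt20: float, cv: float, cutoff: float = WAIT_CUTOFF_DAYS):
    """Gamma (shape, scale) with CDF(cutoff) = p_lt20 at the given CV.

    The shape is pinned by the CV (shape = 1/cv^2); the scale is solved from
    the standard-gamma quantile so the sub-cutoff mass is exact.
    """
    if not 0.0 < p_lt20 < 1.0:
        raise GenerationError("target P(wait<cutoff) must lie in (0, 1)")
    shape = 1.0 / (cv * cv)
    scale = cutoff / float(stats.gamma.ppf(p_lt20, shape))
    return shape, scale


def _empty_cohort() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": pd.Series(dtype="string"),
            "setting": pd.Series(dtype="string"),
            "period": pd.Series(dtype="string"),
            "visit_type": pd.Series(dtype="string"),
            "wait_days": pd.Series(dtype="Int64"),
            "attended": pd.Series(dtype="boolean"),
            "duplicate_test": pd.Series(dtype="boolean"),
            "bill": pd.Series(dtype="float64"),
        }
    )


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw the full synthetic cohort; reproducible given the config's seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    bill_shape = 1.0 / (config.bill_cv * config.bill_cv)
    frames = []
    for setting in SETTINGS:
        for period in PERIODS:
            n = int(config.n_patients.get((setting, period), 0))
            if n == 0:
                continue
            acute = rng.random(n) < config.acute_fraction[period]
            visit_type = np.where(acute, "acute", "chronic")
            means = np.where(
                acute,
                config.bill_means[(setting, period, "acute")],
                config.bill_means[(setting, period, "chronic")],
            )
            # gamma(shape, scale): mean = shape*scale, CV fixed across strata
            bill = rng.gamma(bill_shape, means / bill_shape)
            frame = pd.DataFrame(
                {
                    "patient_id": [f"{setting}-{period}-{i:06d}" for i in range(n)],
                    "setting": setting,
                    "period": period,
                    "visit_type": visit_type,
                    "bill": bill,
                }
            )
            if setting == "SOC":
                shape, scale = waiting_gamma_params(config.p_wait_lt20[period], config.wait_cv)
                wait = np.floor(rng.gamma(shape, scale, n)).astype(np.int64)
                lt20 = wait < WAIT_CUTOFF_DAYS
                p_att = np.where(
                    lt20,
                    config.attendance[(period, "lt20")],
                    config.attendance[(period, "ge20")],
                )
                attended = rng.random(n) < p_att
                duplicate = rng.random(n) < config.p_duplicate[period]
                frame["wait_days"] = pd.array(wait, dtype="Int64")
                frame["attended"] = pd.array(attended, dtype="boolean")
                frame["duplicate_test"] = pd.array(
                    np.where(attended, duplicate, None), dtype="boolean"
                )
                # no-shows generate no bill; duplicate tests add the surcharge
                frame.loc[~attended, "bill"] = 0.0
                dup_mask = attended & duplicate
                frame.loc[dup_mask, "bill"] += config.duplicate_surcharge[period]
            else:
                frame["wait_days"] = pd.array([None] * n, dtype="Int64")
                frame["attended"] = pd.array([None] * n, dtype="boolean")
                frame["duplicate_test"] = pd.array([None] * n, dtype="boolean")
            frames.append(frame[list(COHORT_COLUMNS)])
    if not frames:
        return _empty_cohort()
    out = pd.concat(frames, ignore_index=True)
    out["patient_id"] = out["patient_id"].astype("string")
    for col in ("setting", "period", "visit_type"):
        out[col] = out[col].astype("string")
    return out


def write_cohort(records: pd.DataFrame, path: str | Path, seed: int | None = None) -> None:
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        records.to_csv(fh, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#")
    frame["wait_days"] = frame["wait_days"].astype("Int64")
    for col in ("attended", "duplicate_test"):
        frame[col] = frame[col].astype("boolean")
    for col in ("patient_id", "setting", "period", "visit_type"):
        frame[col] = frame[col].astype("string")
    return frame


def _soc_period(records: pd.DataFrame, period: str) -> pd.DataFrame:
    subset = records[(records["setting"] == "SOC") & (records["period"] == period)]
    if len(subset) == 0:
        raise EstimationError(f"no SOC records in period {period!r}")
    return subset


def _proportion(mask: np.ndarray) -> tuple[float, float]:
    n = mask.size
    p = float(np.mean(mask))
    return p, float(np.sqrt(p * (1.0 - p) / n))


def estimate_waiting_proportion(
    records: pd.DataFrame, period: str, cutoff: float = WAIT_CUTOFF_DAYS
) -> tuple[float, float]:
    """Sample proportion of SOC waits < cutoff, with binomial SE."""
    subset = _soc_period(records, period)
    return _proportion((subset["wait_days"] < cutoff).to_numpy(dtype=bool))


def estimate_attendance(
    records: pd.DataFrame, period: str, stratum: str
) -> tuple[float, float]:
    """Attendance proportion within a wait stratum (``"lt20"``/``"ge20"``)."""
    if stratum not in ("lt20", "ge20"):
        raise ValueError(f"unknown stratum {stratum!r}")
    subset = _soc_period(records, period)
    in_stratum = (
        subset["wait_days"] < WAIT_CUTOFF_DAYS
        if stratum == "lt20"
        else subset["wait_days"] >= WAIT_CUTOFF_DAYS
    )
    subset = subset[in_stratum]
    if len(subset) == 0:
        raise EstimationError(f"no SOC records in period {period!r}, stratum {stratum!r}")
    return _proportion(subset["attended"].to_numpy(dtype=bool))


def _billable(records: pd.DataFrame, setting: str) -> pd.DataFrame:
    subset = records[records["setting"] == setting]
    if setting == "SOC":
        # visit cost without duplicate tests, among realized visits
        subset = subset[(subset["attended"] == True) & (subset["duplicate_test"] == False)]  # noqa: E712
    return subset


def estimate_costs_matched(
    records: pd.DataFrame, setting: str
) -> dict[str, tuple[float, float]]:
    """Per-period mean bill with the post-period reweighted to the pre mix.

    Matching is exact stratified reweighting on visit type: each period's mean
    is the pre-period-mix-weighted average of its stratum means, with SE
    sqrt(sum w_t^2 * var_t / n_t).  For SOC, only attended visits without
    duplicate tests enter (the no-duplicate visit price).
    """
    subset = _billable(records, setting)
    pre = subset[subset["period"] == "pre"]
    if len(pre) == 0:
        raise EstimationError(f"no billable pre-period {setting} records")
    weights = pre["visit_type"].value_counts(normalize=True)
    out: dict[str, tuple[float, float]] = {}
    for period in PERIODS:
        frame = subset[subset["period"] == period]
        if len(frame) == 0:
            raise EstimationError(f"no billable {setting} records in period {period!r}")
        mean = 0.0
        var = 0.0
        for vtype, w in weights.items():
            stratum = frame[frame["visit_type"] == vtype]["bill"]
            if len(stratum) == 0:
                raise MatchingError(
                    f"{setting} period {period!r} has no {vtype!r} visits to match on"
                )
            mean += w * float(stratum.mean())
            var += w * w * float(stratum.var(ddof=1)) / len(stratum) if len(stratum) > 1 else 0.0
        out[period] = (mean, float(np.sqrt(var)))
    return out


def parameters_from_cohort(
    records: pd.DataFrame,
    ancillary: ParameterTable | Mapping[tuple[str, str], DistributionSpec] | None = None,
) -> ParameterTable:
    """Re-estimate the model's data-derived parameters from a cohort.

    Waiting proportions, stratified attendance and visit costs come from the
    records; everything the extracts cannot inform (duplicate tests,
    admissions, ED, admission/ED costs, utilities, the with-duplicate SOC
    price) passes through unchanged from ``ancillary`` (default: the built-in
    literature/assumption entries).
    """
    if ancillary is None:
        ancillary = default_parameters()
    if isinstance(ancillary, ParameterTable):
        ancillary_map = {s.key: s for s in ancillary}
    else:
        ancillary_map = dict(ancillary)
    missing = [k for k in LITERATURE_KEYS if k not in ancillary_map]
    if missing:
        raise EstimationError(f"ancillary specs missing literature parameters: {missing}")

    nup_costs = estimate_costs_matched(records, "NUP")
    soc_costs = estimate_costs_matched(records, "SOC")
    specs: list[DistributionSpec] = []
    for period in PERIODS:
        arm = PERIOD_TO_ARM[period]
        p, se = estimate_waiting_proportion(records, period)
        specs.append(DistributionSpec("p_wait_lt20", arm, "beta", p, se))
        for stratum, name in (("lt20", "p_attend_lt20"), ("ge20", "p_attend_ge20")):
            p, se = estimate_attendance(records, period, stratum)
            specs.append(DistributionSpec(name, arm, "beta", p, se))
        for cname, costs in (("c_nup_visit", nup_costs), ("c_soc_visit", soc_costs)):
            mean, se = costs[period]
            specs.append(DistributionSpec(cname, arm, "gamma", mean, se, role="cost"))
    specs.extend(ancillary_map[k] for k in LITERATURE_KEYS)
    return ParameterTable(tuple(specs))
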