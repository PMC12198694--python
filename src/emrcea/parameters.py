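"""Model input parameters for the EMR-vs-NGEMR cost-utility model.

Every model input is a :class:`DistributionSpec`: a named quantity attached to
one arm (legacy ``EMR``, integrated ``NGEMR``, or ``shared``) with a base-case
mean and an uncertainty distribution (beta for probabilities and utilities,
gamma for costs, or degenerate/fixed).  Beta and gamma distributions are
parameterised by moment matching from the published mean and standard error;
the admission cost instead carries an explicit gamma shape/scale because its
source reported median-based figures without an SD.

The complete set of 21 inputs (base case: 2021 Singapore dollars, one-year
horizon) is available from :func:`default_parameters`, and tables can be
round-tripped through a CSV file with columns
``name, arm, family, mean, se, shape, scale, role``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from scipy import stats

ARMS = ("EMR", "NGEMR")
SHARED = "shared"
FAMILIES = ("beta", "gamma", "fixed")
ROLES = ("probability", "cost", "utility")

__all__ = [
    "ARMS",
    "SHARED",
    "DistributionSpec",
    "ParameterTable",
    "ParameterError",
    "NotApplicableError",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "ci95",
    "iqr_bounds",
    "base_case_value",
    "default_parameters",
    "load_parameters",
]


class ParameterError(ValueError):
    """A parameter specification or table violates its constraints."""


class NotApplicableError(ParameterError):
    """The requested operation has no meaning for this distribution family."""


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Moment-match a beta distribution to a mean and standard error.

    Uses nu = mean(1-mean)/se^2 - 1, alpha = mean*nu, beta = (1-mean)*nu, so
    the returned Beta(alpha, beta) has exactly the requested mean and SD.

    Raises
    ------
    ParameterError
        If ``mean`` is outside (0, 1) or ``se^2 >= mean(1-mean)`` (no beta
        distribution has a variance that large at that mean).
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean must lie in (0, 1), got {mean}")
    if se <= 0.0 or se * se >= mean * (1.0 - mean):
        raise ParameterError(
            f"invalid variance: need 0 < se^2 < mean*(1-mean); "
            f"got se={se} at mean={mean}"
        )
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Moment-match a gamma distribution: shape = mean^2/se^2, scale = se^2/mean."""
    if mean <= 0.0 or se <= 0.0:
        raise ParameterError(f"gamma moment matching needs mean>0, se>0; got ({mean}, {se})")
    return mean * mean / (se * se), se * se / mean


@dataclass(frozen=True)
class DistributionSpec:
    """One named model input with its base-case value and uncertainty model.

    ``mean`` is always the base-case (point-estimate) value used in
    deterministic analyses, even when an explicit ``shape``/``scale`` pair
    implies a different analytic mean (the admission cost: base case 2707 S$
    from median-based fee benchmarks, sampled from gamma(2.06, 1549.32)).
    """

    name: str
    arm: str
    family: str
    mean: float
    se: float | None = None
    shape: float | None = None
    scale: float | None = None
    role: str = "probability"

    def __post_init__(self) -> None:
        if self.arm not in ARMS and self.arm != SHARED:
            raise ParameterError(f"{self.name}: unknown arm {self.arm!r}")
        if self.family not in FAMILIES:
            raise ParameterError(f"{self.name}: unknown family {self.family!r}")
        if self.role not in ROLES:
            raise ParameterError(f"{self.name}: unknown role {self.role!r}")
        if self.role in ("probability", "utility") and not 0.0 <= self.mean <= 1.0:
            raise ParameterError(
                f"{self.name}: {self.role} mean must lie in [0, 1], got {self.mean}"
            )
        if self.family == "fixed":
            if self.se is not None or self.shape is not None or self.scale is not None:
                raise ParameterError(f"{self.name}: fixed parameters take no se/shape/scale")
        elif self.family == "beta":
            if self.se is None:
                raise ParameterError(f"{self.name}: beta parameters need an SE")
            beta_from_mean_se(self.mean, self.se)  # validates the variance bound
        else:  # gamma
            if self.mean <= 0.0:
                raise ParameterError(f"{self.name}: gamma mean must be positive")
            has_se = self.se is not None and self.se > 0.0
            has_shape = (
                self.shape is not None
                and self.scale is not None
                and self.shape > 0.0
                and self.scale > 0.0
            )
            if not (has_se or has_shape):
                raise ParameterError(
                    f"{self.name}: gamma parameters need se>0 or explicit shape>0 and scale>0"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.arm)

    def distribution(self):
        """The scipy frozen uncertainty distribution, or ``None`` for fixed."""
        if self.family == "fixed":
            return None
        if self.family == "beta":
            a, b = beta_from_mean_se(self.mean, self.se)
            return stats.beta(a, b)
        if self.shape is not None and self.scale is not None:
            return stats.gamma(self.shape, scale=self.scale)
        shape, scale = gamma_from_mean_se(self.mean, self.se)
        return stats.gamma(shape, scale=scale)


def base_case_value(spec: DistributionSpec) -> float:
    """The deterministic base-case value: always the printed mean."""
    return spec.mean


def ci95(spec: DistributionSpec) -> tuple[float, float]:
    """95% interval (2.5%/97.5% quantiles) of the parameter's distribution.

    Fixed parameters return a degenerate ``(mean, mean)`` interval.
    """
    dist = spec.distribution()
    if dist is None:
        return (spec.mean, spec.mean)
    return (float(dist.ppf(0.025)), float(dist.ppf(0.975)))


def iqr_bounds(spec: DistributionSpec) -> tuple[float, float]:
    """Interquartile bounds (25%/75% quantiles), for parameters whose SD is
    unavailable and whose sensitivity range is IQR-based."""
    dist = spec.distribution()
    if dist is None:
        raise NotApplicableError(f"{spec.name}: IQR bounds undefined for a fixed parameter")
    return (float(dist.ppf(0.25)), float(dist.ppf(0.75)))


def _spec(name, arm, family, mean, se=None, shape=None, scale=None, role="probability"):
    return DistributionSpec(name, arm, family, mean, se, shape, scale, role)


def _default_entries() -> tuple[DistributionSpec, ...]:
    # Probabilities and utilities: beta; costs: gamma; ED visit cost: fixed
    # (no uncertainty distribution is available for it).  Where the source
    # text is more precise than the rounded summary table, the precise value
    # is used (attendance <20d EMR 86.6%, NGEMR waiting proportion 45.5%,
    # duplicate tests 29.4%/20.7%, admission 11.83%/11.55%).
    return (
        _spec("p_wait_lt20", "EMR", "beta", 0.37, 0.004),
        _spec("p_wait_lt20", "NGEMR", "beta", 0.455, 0.004),
        _spec("p_attend_lt20", "EMR", "beta", 0.866, 0.005),
        _spec("p_attend_lt20", "NGEMR", "beta", 0.88, 0.004),
        _spec("p_attend_ge20", "EMR", "beta", 0.82, 0.004),
        _spec("p_attend_ge20", "NGEMR", "beta", 0.80, 0.004),
        _spec("p_duplicate", "EMR", "beta", 0.294, 0.05),
        _spec("p_duplicate", "NGEMR", "beta", 0.207, 0.04),
        _spec("p_admission", "EMR", "beta", 0.1183, 0.002),
        _spec("p_admission", "NGEMR", "beta", 0.1155, 0.002),
        _spec("p_ed_admission", SHARED, "beta", 0.30, 0.002),
        _spec("c_nup_visit", "EMR", "gamma", 102.30, 0.25, role="cost"),
        _spec("c_nup_visit", "NGEMR", "gamma", 114.73, 0.28, role="cost"),
        _spec("c_soc_visit", "EMR", "gamma", 189.07, 0.92, role="cost"),
        _spec("c_soc_visit", "NGEMR", "gamma", 191.67, 1.09, role="cost"),
        _spec("c_soc_visit_duplicate", "EMR", "gamma", 266.04, 0.94, role="cost"),
        _spec("c_soc_visit_duplicate", "NGEMR", "gamma", 270.41, 1.12, role="cost"),
        _spec("c_admission", SHARED, "gamma", 2707.0, shape=2.06, scale=1549.32, role="cost"),
        _spec("c_ed_visit", SHARED, "fixed", 141.0, role="cost"),
        _spec("u_admitted", SHARED, "beta", 0.89, 0.019, role="utility"),
        _spec("u_nonadmitted", SHARED, "beta", 0.91, 0.01, role="utility"),
    )


CANONICAL_KEYS: tuple[tuple[str, str], ...] = tuple(s.key for s in _default_entries())

#: (name, arm) keys whose values come from literature/assumption rather than
#: from the visit-level billing extracts.
LITERATURE_KEYS: tuple[tuple[str, str], ...] = (
    ("p_duplicate", "EMR"),
    ("p_duplicate", "NGEMR"),
    ("p_admission", "EMR"),
    ("p_admission", "NGEMR"),
    ("p_ed_admission", SHARED),
    ("c_soc_visit_duplicate", "EMR"),
    ("c_soc_visit_duplicate", "NGEMR"),
    ("c_admission", SHARED),
    ("c_ed_visit", SHARED),
    ("u_admitted", SHARED),
    ("u_nonadmitted", SHARED),
)


@dataclass(frozen=True)
class ParameterTable:
    """The complete, validated set of model inputs for both arms.

    Lookups by ``(name, arm)`` fall back to the shared entry, so
    ``table.get("c_admission", "EMR")`` resolves the shared admission cost.
    """

    entries: tuple[DistributionSpec, ...]
    metadata: Mapping[str, str] = field(
        default_factory=lambda: {"currency": "SGD", "currency_year": "2021"}
    )

    def __post_init__(self) -> None:
        keys = [s.key for s in self.entries]
        dupes = {k for k in keys if keys.count(k) > 1}
        if dupes:
            raise ParameterError(f"duplicate parameter entries: {sorted(dupes)}")
        missing = set(CANONICAL_KEYS) - set(keys)
        extra = set(keys) - set(CANONICAL_KEYS)
        if missing:
            raise ParameterError(f"missing parameters: {sorted(missing)}")
        if extra:
            raise ParameterError(f"unknown parameters: {sorted(extra)}")

    def __iter__(self) -> Iterator[DistributionSpec]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str, arm: str) -> DistributionSpec:
        by_key = {s.key: s for s in self.entries}
        if (name, arm) in by_key:
            return by_key[(name, arm)]
        if (name, SHARED) in by_key:
            return by_key[(name, SHARED)]
        raise ParameterError(f"no parameter {name!r} for arm {arm!r}")

    def value(self, name: str, arm: str) -> float:
        return base_case_value(self.get(name, arm))

    def base_case_mapping(self) -> dict[tuple[str, str], float]:
        """Base-case values keyed by (name, arm) — the tree-builder contract."""
        return {s.key: base_case_value(s) for s in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": s.name,
                    "arm": s.arm,
                    "family": s.family,
                    "mean": s.mean,
                    "se": s.se,
                    "shape": s.shape,
                    "scale": s.scale,
                    "role": s.role,
                }
                for s in self.entries
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | Path | None = None) -> str:
        """Normalised JSON echo of the table (provenance record)."""
        payload = {
            "metadata": dict(self.metadata),
            "sha256": self.sha256(),
            "entries": self.to_frame().to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text

    def sha256(self) -> str:
        return hashlib.sha256(self.to_frame().to_csv(index=False).encode()).hexdigest()


def default_parameters() -> ParameterTable:
    """The built-in base-case parameter table (21 entries, 2021 S$)."""
    return ParameterTable(_default_entries())


_CSV_COLUMNS = ["name", "arm", "family", "mean", "se", "shape", "scale", "role"]


def load_parameters(path: str | Path | None = None) -> ParameterTable:
    """Load and validate a parameter table from CSV; defaults when no file given.

    The CSV must carry a header with columns ``name, arm, family, mean, se,
    shape, scale, role``; blank cells mean "not applicable".  Errors name the
    offending row.
    """
    if path is None:
        return default_parameters()
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"parameter file not found: {path}")
    frame = pd.read_csv(path, comment="#")
    missing_cols = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise ParameterError(f"parameter file {path} lacks columns {missing_cols}")
    specs = []
    for i, row in frame.iterrows():
        def _opt(col):
            val = row[col]
            return None if pd.isna(val) else float(val)

        try:
            specs.append(
                DistributionSpec(
                    name=str(row["name"]),
                    arm=str(row["arm"]),
                    family=str(row["family"]),
                    mean=float(row["mean"]),
                    se=_opt("se"),
                    shape=_opt("shape"),
                    scale=_opt("scale"),
                    role=str(row["role"]),
                )
            )
        except (ParameterError, ValueError) as err:
            raise ParameterError(
                f"{path} row {i} ({row['name']}, {row['arm']}): {err}"
            ) from err
    return ParameterTable(tuple(specs))
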