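"""Domain types for the presbyopia productivity-burden model.

The model works with four kinds of inputs — case counts of uncorrected /
under-corrected presbyopia by 5-year age band (GBD-style, with 95%
uncertainty bounds), macro-economic profiles (GDP per capita, total GDP,
employment-to-population ratio, labour-force participation rate), and
age-specific mortality schedules — plus two parameter blocks: the
productivity index inputs (presenteeism, absenteeism) and the simulation
configuration (discount rate, retirement age, base year).

All ratios are stored as fractions in [0, 1], never percentages; input
files carrying percentages must be pre-scaled.  Age bands are closed
integer intervals [lower, lower + 4].
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "INCOME_GROUPS",
    "AgeGroup",
    "PrevalenceRecord",
    "EconProfile",
    "MortalitySchedule",
    "ProductivityParams",
    "ModelConfig",
    "ValidationError",
    "SchemaError",
]

#: World Bank style income strata used for aggregation, ordered poorest first.
INCOME_GROUPS = ("low", "lower_middle", "upper_middle")


class ValidationError(ValueError):
    """An input record violates a model invariant."""


class SchemaError(ValidationError):
    """An input table is missing required columns or uses unknown ones."""


@dataclass(frozen=True, order=True)
class AgeGroup:
    """Closed five-year age band [lower, upper], e.g. 40-44."""

    lower: int
    upper: int

    def __post_init__(self) -> None:
        if self.lower % 5 != 0:
            raise ValidationError(
                f"age band must start on a multiple of 5, got {self.lower}"
            )
        if self.upper != self.lower + 4:
            raise ValidationError(
                f"age band must span 5 years, got [{self.lower}, {self.upper}]"
            )

    @classmethod
    def from_lower(cls, lower: int) -> "AgeGroup":
        return cls(int(lower), int(lower) + 4)

    @property
    def midpoint(self) -> int:
        """Central integer age of the band; cohorts start simulation here."""
        return self.lower + 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.lower}-{self.upper}"


@dataclass(frozen=True)
class PrevalenceRecord:
    """Cases of the condition for one country and 5-year age band.

    ``cases`` is the point estimate of the number of affected persons;
    ``cases_lower``/``cases_upper`` carry the 95% uncertainty bounds.
    When a source provides no bounds, both default to the point estimate.
    """

    country_id: str
    income_group: str
    age_group: AgeGroup
    cases: float
    cases_lower: float = None  # type: ignore[assignment]
    cases_upper: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.income_group not in INCOME_GROUPS:
            raise ValidationError(
                f"unknown income group {self.income_group!r}; "
                f"expected one of {INCOME_GROUPS}"
            )
        if self.cases_lower is None:
            object.__setattr__(self, "cases_lower", self.cases)
        if self.cases_upper is None:
            object.__setattr__(self, "cases_upper", self.cases)
        for name in ("cases", "cases_lower", "cases_upper"):
            v = getattr(self, name)
            if not v >= 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")
        if not (self.cases_lower <= self.cases <= self.cases_upper):
            raise ValidationError(
                f"case bounds must satisfy lower <= point <= upper, got "
                f"{self.cases_lower} / {self.cases} / {self.cases_upper}"
            )

    def bounded_cases(self, bound: str = "point") -> float:
        """Point estimate or one of the uncertainty bounds."""
        if bound == "point":
            return self.cases
        if bound == "lower":
            return self.cases_lower
        if bound == "upper":
            return self.cases_upper
        raise ValueError(f"unknown case bound {bound!r}")


@dataclass(frozen=True)
class EconProfile:
    """Macro-economic inputs for one country.

    ``employment_ratio`` (ER) is employed persons over working-age
    population; ``labor_participation`` (LPR) is the economically active
    share.  The employed are a subset of the active, so ER <= LPR.
    Monetary values are current US$ of the base year.
    """

    country_id: str
    gdp_per_capita: float
    gdp_total: float
    employment_ratio: float
    labor_participation: float

    def __post_init__(self) -> None:
        for name in ("gdp_per_capita", "gdp_total"):
            if not getattr(self, name) > 0:
                raise ValidationError(
                    f"{name} must be strictly positive, got {getattr(self, name)}"
                )
        for name in ("employment_ratio", "labor_participation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{name} must be a fraction in [0, 1], got {v} "
                    "(percentages must be pre-scaled)"
                )
        if self.employment_ratio > self.labor_participation:
            raise ValidationError(
                f"employment_ratio {self.employment_ratio} exceeds "
                f"labor_participation {self.labor_participation}"
            )


@dataclass(frozen=True)
class MortalitySchedule:
    """Annual death probabilities q(a) by single year of age."""

    country_id: str
    q: dict[int, float]

    def __post_init__(self) -> None:
        for age, prob in self.q.items():
            if not 0.0 <= prob <= 1.0:
                raise ValidationError(
                    f"death probability at age {age} outside [0, 1]: {prob}"
                )

    def require_coverage(self, start_age: int, last_age: int) -> None:
        """Raise if any integer age in [start_age, last_age] lacks a q."""
        missing = [a for a in range(start_age, last_age + 1) if a not in self.q]
        if missing:
            raise ValidationError(
                f"mortality schedule for {self.country_id} missing "
                f"age(s) {missing}"
            )


@dataclass(frozen=True)
class ProductivityParams:
    """Inputs to the productivity index.

    The affected cohort's index is
    ``1 - presenteeism - absenteeism_days / workdays_per_year``;
    the unaffected cohort's index is exactly 1.  Defaults are the pooled
    10.9% presenteeism estimate with zero absenteeism.
    """

    presenteeism: float = 0.109
    absenteeism_days: float = 0.0
    workdays_per_year: float = 250.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.presenteeism <= 1.0:
            raise ValidationError(
                f"presenteeism must be in [0, 1], got {self.presenteeism}"
            )
        if self.absenteeism_days < 0:
            raise ValidationError("absenteeism_days must be non-negative")
        if self.workdays_per_year <= 0:
            raise ValidationError("workdays_per_year must be positive")
        if self.loss_fraction > 1.0:
            raise ValidationError(
                "presenteeism + absenteeism fraction exceeds 1; "
                "the affected productivity index would be negative"
            )

    @property
    def absenteeism_fraction(self) -> float:
        return self.absenteeism_days / self.workdays_per_year

    @property
    def loss_fraction(self) -> float:
        """Per-year productivity lost by an affected person, in [0, 1]."""
        return self.presenteeism + self.absenteeism_fraction

    def scaled(self, presenteeism_multiplier: float) -> "ProductivityParams":
        """Copy with presenteeism scaled (scenario analyses)."""
        return ProductivityParams(
            presenteeism=self.presenteeism * presenteeism_multiplier,
            absenteeism_days=self.absenteeism_days,
            workdays_per_year=self.workdays_per_year,
        )


@dataclass(frozen=True)
class ModelConfig:
    """Simulation configuration.

    discount_rate: annual rate converting future person-years/PALYs to
        present value (WHO standard 3%).
    retirement_age: simulation stops when the cohort reaches this age.
    base_year: calendar year of the cross-sectional inputs; the first
        simulated year is undiscounted.
    """

    discount_rate: float = 0.03
    retirement_age: int = 65
    base_year: int = 2019

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")
        if self.retirement_age <= 0:
            raise ValidationError("retirement_age must be positive")

    def with_rate(self, rate: float) -> "ModelConfig":
        return ModelConfig(
            discount_rate=rate,
            retirement_age=self.retirement_age,
            base_year=self.base_year,
        )
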