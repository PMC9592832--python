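"""Monetary valuation and aggregation of productivity losses.

The total productivity loss (TPL) values PALYs lost at GDP per capita:

    TPL = TC x ER x LPR x PALYs lost per person x GDP(PC)

where TC is the working-age case count, ER the employment-to-population
ratio and LPR the labour-force participation rate.  Both ER and LPR are
multiplied, exactly as the formula states, even though ER already embeds
participation; see the methods note for discussion.  If a profile is
built with GDP per full-time worker in the ``gdp_per_capita`` slot the
same formula yields the per-worker valuation.

Aggregation sums cases, PALYs and dollars within a stratum and recomputes
ratio columns from the summed numerators and denominators — ratios are
never averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .datatypes import INCOME_GROUPS, EconProfile, ProductivityParams, ValidationError

__all__ = [
    "BurdenResult",
    "lifetime_loss",
    "annual_loss",
    "gdp_share",
    "per_person",
    "aggregate",
    "top_k_share",
    "results_to_frame",
]


@dataclass(frozen=True)
class BurdenResult:
    """Productivity-burden summary for one scope (country, stratum, total).

    ``gdp_total`` is carried so that loss/GDP shares of aggregates can be
    recomputed from summed denominators; it is NaN when unknown.
    """

    scope: str  # "country" | "income_group" | "total"
    scope_id: str
    cases: float
    palys_lost: float
    gdp_lost: float
    per_person_usd: float
    loss_gdp_pct: float
    gdp_total: float = math.nan
    income_group: str | None = None

    def __post_init__(self) -> None:
        if self.gdp_lost < 0:
            raise ValidationError(f"gdp_lost must be >= 0, got {self.gdp_lost}")


def lifetime_loss(
    cases: float, econ: EconProfile, palys_lost_per_person: float
) -> float:
    """TPL over the working lifetime, in current US$."""
    if cases < 0 or palys_lost_per_person < 0:
        raise ValidationError("cases and PALYs lost per person must be >= 0")
    return (
        cases
        * econ.employment_ratio
        * econ.labor_participation
        * palys_lost_per_person
        * econ.gdp_per_capita
    )


def annual_loss(
    cases: float, econ: EconProfile, params: ProductivityParams
) -> float:
    """Cross-sectional one-year loss: the TPL formula with PALYs lost per
    person equal to the per-year loss fraction (one undiscounted year)."""
    return lifetime_loss(cases, econ, params.loss_fraction)


def gdp_share(loss: float, gdp_total: float) -> float:
    """Loss as a percentage of total GDP."""
    if gdp_total <= 0:
        raise ValidationError(f"gdp_total must be positive, got {gdp_total}")
    return 100.0 * loss / gdp_total


def per_person(loss: float, cases: float) -> float:
    """Average US$ lost per affected person."""
    if cases <= 0:
        raise ValidationError(
            f"per-person loss undefined for cases = {cases}"
        )
    return loss / cases


def _combine(results: list[BurdenResult], scope: str, scope_id: str) -> BurdenResult:
    cases = sum(r.cases for r in results)
    palys = sum(r.palys_lost for r in results)
    loss = sum(r.gdp_lost for r in results)
    gdp = sum(r.gdp_total for r in results)  # NaN-propagating on purpose
    return BurdenResult(
        scope=scope,
        scope_id=scope_id,
        cases=cases,
        palys_lost=palys,
        gdp_lost=loss,
        per_person_usd=loss / cases if cases > 0 else 0.0,
        loss_gdp_pct=100.0 * loss / gdp if gdp > 0 else math.nan,
        gdp_total=gdp,
    )


def aggregate(
    results: Iterable[BurdenResult], by: str = "income_group"
) -> list[BurdenResult]:
    """Roll country results up to income-group strata or a single total.

    Extensive columns (cases, PALYs lost, dollars) are summed; per-person
    and loss/GDP are recomputed from the sums.
    """
    results = list(results)
    if by == "total":
        return [_combine(results, "total", "total")]
    if by != "income_group":
        raise ValueError(f"unknown aggregation key {by!r}")
    for r in results:
        if r.income_group not in INCOME_GROUPS:
            raise ValidationError(
                f"result {r.scope_id!r} has unknown income group "
                f"{r.income_group!r}"
            )
    out = []
    for group in INCOME_GROUPS:
        members = [r for r in results if r.income_group == group]
        if members:
            agg = _combine(members, "income_group", group)
            out.append(replace(agg, income_group=group))
    return out


def top_k_share(results: Iterable[BurdenResult], k: int) -> float:
    """Share (%) of total GDP lost concentrated in the k biggest losers.

    Ties are broken lexicographically by scope_id so the result is
    deterministic.
    """
    results = list(results)
    if not results:
        raise ValidationError("top_k_share requires at least one result")
    if not 1 <= k <= len(results):
        raise ValidationError(
            f"k must be in [1, {len(results)}], got {k}"
        )
    total = sum(r.gdp_lost for r in results)
    if total <= 0:
        raise ValidationError("total GDP lost must be positive")
    ranked = sorted(results, key=lambda r: (-r.gdp_lost, r.scope_id))
    return 100.0 * sum(r.gdp_lost for r in ranked[:k]) / total


def results_to_frame(results: Iterable[BurdenResult]) -> pd.DataFrame:
    """Full-precision tabular form matching the results.csv schema."""
    results = list(results)
    return pd.DataFrame(
        {
            "scope": [r.scope for r in results],
            "scope_id": [r.scope_id for r in results],
            "cases": [r.cases for r in results],
            "palys_lost": [r.palys_lost for r in results],
            "gdp_lost_usd": [r.gdp_lost for r in results],
            "per_person_usd": [r.per_person_usd for r in results],
            "loss_gdp_pct": [r.loss_gdp_pct for r in results],
        }
    )
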