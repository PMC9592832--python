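"""CSV readers and writers for the four model table schemas.

Schemas (UTF-8, header row, "." decimal separator):

prevalence.csv
    country_id, income_group, age_lower, cases[, cases_lower, cases_upper]
econ.csv
    country_id, gdp_per_capita, gdp_total, employment_ratio,
    labor_participation
mortality.csv — one of two layouts:
    country_id, age, q            (single-year annual probabilities)
    country_id, age_lower, q5     (5-year-band probabilities, expanded to
                                   annual via ``annual_prob_from_band``)
results.csv (output)
    scope, scope_id, cases, palys_lost, gdp_lost_usd, per_person_usd,
    loss_gdp_pct

Readers validate every row against the type invariants and report the
offending row index in the error message.  Ratios are read as fractions
(0.62), never percentages.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd

from .datatypes import (
    AgeGroup,
    EconProfile,
    MortalitySchedule,
    PrevalenceRecord,
    SchemaError,
    ValidationError,
)

__all__ = [
    "annual_prob_from_band",
    "load_prevalence",
    "load_econ",
    "load_mortality",
    "prevalence_from_frame",
    "econ_from_frame",
    "mortality_from_frame",
    "prevalence_to_frame",
    "econ_to_frame",
    "mortality_to_frame",
    "write_prevalence",
    "write_econ",
    "write_mortality",
    "write_results",
]


def annual_prob_from_band(q5: float, band_width: int) -> float:
    """Annual death probability equivalent to a multi-year band probability.

    Solves ``1 - (1 - q)**band_width = q5`` for q, so that surviving
    ``band_width`` years at the returned annual probability reproduces the
    band survival exactly.
    """
    if not 0.0 <= q5 <= 1.0:
        raise ValidationError(f"band probability must be in [0, 1], got {q5}")
    if band_width < 1:
        raise ValidationError(f"band_width must be >= 1, got {band_width}")
    if q5 == 1.0:
        return 1.0
    return 1.0 - (1.0 - q5) ** (1.0 / band_width)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{what} table is missing required column(s): {', '.join(missing)}"
        )


def prevalence_from_frame(df: pd.DataFrame) -> list[PrevalenceRecord]:
    _require_columns(
        df, ["country_id", "income_group", "age_lower", "cases"], "prevalence"
    )
    has_bounds = "cases_lower" in df.columns and "cases_upper" in df.columns
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                PrevalenceRecord(
                    country_id=str(row["country_id"]),
                    income_group=str(row["income_group"]),
                    age_group=AgeGroup.from_lower(int(row["age_lower"])),
                    cases=float(row["cases"]),
                    cases_lower=float(row["cases_lower"]) if has_bounds else None,
                    cases_upper=float(row["cases_upper"]) if has_bounds else None,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"prevalence row {idx}: {err}") from err
    return records


def econ_from_frame(df: pd.DataFrame) -> list[EconProfile]:
    _require_columns(
        df,
        [
            "country_id",
            "gdp_per_capita",
            "gdp_total",
            "employment_ratio",
            "labor_participation",
        ],
        "econ",
    )
    profiles = []
    for idx, row in df.iterrows():
        try:
            profiles.append(
                EconProfile(
                    country_id=str(row["country_id"]),
                    gdp_per_capita=float(row["gdp_per_capita"]),
                    gdp_total=float(row["gdp_total"]),
                    employment_ratio=float(row["employment_ratio"]),
                    labor_participation=float(row["labor_participation"]),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"econ row {idx}: {err}") from err
    return profiles


def mortality_from_frame(df: pd.DataFrame) -> list[MortalitySchedule]:
    """Build one schedule per country from single-year or banded layout."""
    if "q" in df.columns and "age" in df.columns:
        banded = False
    elif "q5" in df.columns and "age_lower" in df.columns:
        banded = True
    else:
        raise SchemaError(
            "mortality table must have columns (country_id, age, q) or "
            "(country_id, age_lower, q5)"
        )
    _require_columns(df, ["country_id"], "mortality")
    schedules = []
    for country_id, group in df.groupby("country_id", sort=True):
        q: dict[int, float] = {}
        for idx, row in group.iterrows():
            try:
                if banded:
                    lower = int(row["age_lower"])
                    annual = annual_prob_from_band(float(row["q5"]), 5)
                    for age in range(lower, lower + 5):
                        q[age] = annual
                else:
                    q[int(row["age"])] = float(row["q"])
            except ValidationError as err:
                raise ValidationError(f"mortality row {idx}: {err}") from err
        schedules.append(MortalitySchedule(country_id=str(country_id), q=q))
    return schedules


def load_prevalence(path: str | os.PathLike) -> list[PrevalenceRecord]:
    """Read and validate a prevalence CSV."""
    return prevalence_from_frame(pd.read_csv(path))


def load_econ(path: str | os.PathLike) -> list[EconProfile]:
    """Read and validate an economic-profile CSV."""
    return econ_from_frame(pd.read_csv(path))


def load_mortality(
    path: str | os.PathLike, *, min_age: int | None = None, max_age: int = 64
) -> list[MortalitySchedule]:
    """Read a mortality CSV; optionally enforce age coverage up front."""
    schedules = mortality_from_frame(pd.read_csv(path))
    if min_age is not None:
        for sched in schedules:
            sched.require_coverage(min_age, max_age)
    return schedules


def prevalence_to_frame(records: Iterable[PrevalenceRecord]) -> pd.DataFrame:
    records = list(records)
    return pd.DataFrame(
        {
            "country_id": [r.country_id for r in records],
            "income_group": [r.income_group for r in records],
            "age_lower": [r.age_group.lower for r in records],
            "cases": [r.cases for r in records],
            "cases_lower": [r.cases_lower for r in records],
            "cases_upper": [r.cases_upper for r in records],
        }
    )


def econ_to_frame(profiles: Iterable[EconProfile]) -> pd.DataFrame:
    profiles = list(profiles)
    return pd.DataFrame(
        {
            "country_id": [p.country_id for p in profiles],
            "gdp_per_capita": [p.gdp_per_capita for p in profiles],
            "gdp_total": [p.gdp_total for p in profiles],
            "employment_ratio": [p.employment_ratio for p in profiles],
            "labor_participation": [p.labor_participation for p in profiles],
        }
    )


def mortality_to_frame(schedules: Iterable[MortalitySchedule]) -> pd.DataFrame:
    rows = [
        {"country_id": s.country_id, "age": age, "q": prob}
        for s in schedules
        for age, prob in sorted(s.q.items())
    ]
    return pd.DataFrame(rows, columns=["country_id", "age", "q"])


def write_prevalence(records: Iterable[PrevalenceRecord], path) -> None:
    prevalence_to_frame(records).to_csv(path, index=False)


def write_econ(profiles: Iterable[EconProfile], path) -> None:
    econ_to_frame(profiles).to_csv(path, index=False)


def write_mortality(schedules: Iterable[MortalitySchedule], path) -> None:
    mortality_to_frame(schedules).to_csv(path, index=False)


def write_results(results, path) -> None:
    """Write burden results to results.csv at full precision."""
    from .economics import results_to_frame

    results_to_frame(results).to_csv(path, index=False)
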