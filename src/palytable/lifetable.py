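"""Deterministic cohort life-table engine.

A cohort entering at ``start_age`` is followed in annual cycles until the
retirement age.  Each year t the survivors at the start of the year live a
full person-year and a fraction q(start_age + t) of them dies at year end:

    survivors[t+1] = survivors[t] * (1 - q(start_age + t))
    person_years[t] = survivors[t]

Deaths occur at year end, so decedents contribute a full person-year in
their death year (no half-cycle correction).  Persons are fractional: this
is an expected-value model, not a micro-simulation.  Present-value
weighting uses discrete annual factors (1 + r)^-t with the first simulated
year undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ModelConfig, MortalitySchedule, ValidationError

__all__ = [
    "CohortTrajectory",
    "discount_factors",
    "simulate_cohort",
    "discounted_person_years",
]


@dataclass(frozen=True)
class CohortTrajectory:
    """Year-by-year bookkeeping for one simulated cohort.

    ``survivors`` has T + 1 entries: persons alive at the start of each of
    the T simulated years plus the count reaching retirement.  ``deaths``,
    ``person_years`` and ``discounted_person_years`` each have T entries.
    """

    start_age: int
    initial_count: float
    survivors: np.ndarray
    deaths: np.ndarray
    person_years: np.ndarray
    discounted_person_years: np.ndarray

    @property
    def n_years(self) -> int:
        return len(self.person_years)

    @property
    def total_deaths(self) -> float:
        return float(self.deaths.sum())

    @property
    def total_person_years(self) -> float:
        return float(self.person_years.sum())

    @property
    def total_discounted_person_years(self) -> float:
        return float(self.discounted_person_years.sum())

    def to_frame(self):
        """Tabular export: one row per simulated year."""
        import pandas as pd

        return pd.DataFrame(
            {
                "year": np.arange(self.n_years),
                "age": self.start_age + np.arange(self.n_years),
                "survivors": self.survivors[:-1],
                "deaths": self.deaths,
                "person_years": self.person_years,
                "discounted_person_years": self.discounted_person_years,
            }
        )


def discount_factors(T: int, rate: float) -> np.ndarray:
    """Present-value factors (1 + rate)^-t for t = 0 .. T-1."""
    if T < 1:
        raise ValidationError(f"horizon T must be >= 1, got {T}")
    if rate < 0:
        raise ValidationError(f"discount rate must be >= 0, got {rate}")
    return (1.0 + rate) ** -np.arange(T, dtype=float)


def simulate_cohort(
    initial_count: float,
    start_age: int,
    schedule: MortalitySchedule,
    config: ModelConfig,
) -> CohortTrajectory:
    """Follow a cohort from ``start_age`` until the retirement age.

    Simulates T = retirement_age - start_age annual cycles; the schedule
    must provide q for every age in [start_age, retirement_age - 1].
    """
    if initial_count < 0:
        raise ValidationError(f"initial_count must be >= 0, got {initial_count}")
    T = config.retirement_age - start_age
    if T < 1:
        raise ValidationError(
            f"start_age {start_age} must be below retirement age "
            f"{config.retirement_age}"
        )
    schedule.require_coverage(start_age, config.retirement_age - 1)

    q = np.array([schedule.q[start_age + t] for t in range(T)], dtype=float)
    survivors = np.empty(T + 1)
    survivors[0] = initial_count
    np.cumprod(1.0 - q, out=survivors[1:])
    survivors[1:] *= initial_count

    deaths = survivors[:-1] - survivors[1:]
    person_years = survivors[:-1].copy()
    dpy = person_years * discount_factors(T, config.discount_rate)
    return CohortTrajectory(
        start_age=start_age,
        initial_count=float(initial_count),
        survivors=survivors,
        deaths=deaths,
        person_years=person_years,
        discounted_person_years=dpy,
    )


def discounted_person_years(traj: CohortTrajectory, rate: float) -> float:
    """Total present-value person-years of a trajectory at a given rate.

    Equals the undiscounted total when rate = 0.
    """
    return float(
        (traj.person_years * discount_factors(traj.n_years, rate)).sum()
    )
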