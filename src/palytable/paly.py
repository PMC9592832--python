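"""Productivity-adjusted life years (PALYs).

A PALY is a year of life lived weighted by a productivity index in
[0, 1] — the productivity analogue of a QALY.  The affected ("presbyopia")
cohort carries index 1 - presenteeism - absenteeism_fraction; the same
cohort re-simulated without the condition carries index 1.  The condition
is non-fatal, so both cohorts share one mortality trajectory and the PALY
difference reduces analytically to

    PALYs lost = (presenteeism + absenteeism_fraction)
                 x discounted person-years.

That identity (lost fraction == loss_fraction, for every mortality
schedule and discount rate) is a structural property of the model and is
asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import ProductivityParams, ValidationError
from .lifetable import CohortTrajectory, discounted_person_years

__all__ = ["ProductivityIndex", "productivity_index", "palys", "palys_lost"]


@dataclass(frozen=True)
class ProductivityIndex:
    """Fraction of full productivity retained; 1 = fully productive."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValidationError(
                f"productivity index must be in [0, 1], got {self.value}"
            )


def productivity_index(
    params: ProductivityParams, affected: bool
) -> ProductivityIndex:
    """Index for the affected or unaffected cohort.

    Unaffected persons are fully productive by definition; affected
    persons lose ``presenteeism`` plus the absenteeism day fraction.
    With the defaults (10.9% presenteeism, 0 absenteeism) the affected
    index is 0.891.
    """
    if not affected:
        return ProductivityIndex(1.0)
    return ProductivityIndex(1.0 - params.loss_fraction)


def palys(traj: CohortTrajectory, index: ProductivityIndex, rate: float) -> float:
    """Discounted PALYs lived by a cohort: person-years x index."""
    return discounted_person_years(traj, rate) * index.value


def palys_lost(
    traj: CohortTrajectory, params: ProductivityParams, rate: float
) -> float:
    """PALY difference between the unaffected and affected cohort.

    Both cohorts follow the same trajectory (no excess mortality), so the
    loss is loss_fraction x discounted person-years exactly.
    """
    healthy = palys(traj, productivity_index(params, affected=False), rate)
    affected = palys(traj, productivity_index(params, affected=True), rate)
    return healthy - affected
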