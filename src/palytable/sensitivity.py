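"""Deterministic one-way scenario engine.

Each scenario re-runs the entire pipeline with one input perturbed:
the case count swapped to its lower/upper uncertainty bound, the
presenteeism estimate scaled (x0.75 / x1.25 in the standard grid), or the
discount rate moved off the 3% base (to 5% or 1.5%).  Re-running the whole
pipeline (rather than rescaling outputs) keeps interactions representable,
while reproducing the one-at-a-time grid exactly.

Because PALYs lost is linear in presenteeism, a presenteeism multiplier m
changes total PALYs lost by exactly (m - 1) x 100 percent on any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import ModelConfig, ProductivityParams, ValidationError
from .economics import BurdenResult
from .pipeline import Dataset, run_pipeline

__all__ = [
    "ScenarioSpec",
    "BASE_SCENARIO",
    "standard_grid",
    "run_scenario",
    "percent_change",
    "sensitivity_table",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """One deterministic scenario: which single input moves, and where to."""

    name: str
    case_bound: str = "point"  # "point" | "lower" | "upper"
    presenteeism_multiplier: float = 1.0
    discount_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.case_bound not in ("point", "lower", "upper"):
            raise ValidationError(f"unknown case bound {self.case_bound!r}")
        if self.presenteeism_multiplier <= 0:
            raise ValidationError("presenteeism_multiplier must be > 0")
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")


BASE_SCENARIO = ScenarioSpec(name="Base")


def standard_grid() -> list[ScenarioSpec]:
    """The six standard one-way scenarios around the base case."""
    return [
        ScenarioSpec("Upper uncertainty bound of cases", case_bound="upper"),
        ScenarioSpec("Lower uncertainty bound of cases", case_bound="lower"),
        ScenarioSpec(
            "Productivity indices upper uncertainty bound",
            presenteeism_multiplier=1.25,
        ),
        ScenarioSpec(
            "Productivity indices lower uncertainty bound",
            presenteeism_multiplier=0.75,
        ),
        ScenarioSpec("Annual discount rate 5%", discount_rate=0.05),
        ScenarioSpec("Annual discount rate 1.5%", discount_rate=0.015),
    ]


def run_scenario(
    dataset: Dataset,
    spec: ScenarioSpec,
    params: ProductivityParams | None = None,
    config: ModelConfig | None = None,
) -> BurdenResult:
    """Total-scope lifetime burden under one scenario.

    The base spec reproduces the plain pipeline result identically.
    """
    params = (params or ProductivityParams()).scaled(spec.presenteeism_multiplier)
    config = (config or ModelConfig()).with_rate(spec.discount_rate)
    result = run_pipeline(dataset, params, config, case_bound=spec.case_bound)
    return result.total_lifetime


def percent_change(base: BurdenResult, scenario: BurdenResult) -> float:
    """% change in PALYs lost of a scenario relative to the base case."""
    if base.palys_lost <= 0:
        raise ValidationError(
            "percent change undefined for non-positive base PALYs lost"
        )
    return 100.0 * (scenario.palys_lost - base.palys_lost) / base.palys_lost


def sensitivity_table(
    dataset: Dataset,
    specs: list[ScenarioSpec] | None = None,
    params: ProductivityParams | None = None,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """One row per scenario, base row first.

    Columns: analysis, palys_lost, pct_change (vs base), gdp_lost_usd,
    per_person_usd.  Per-person figures use each scenario's own case
    count (relevant for the bound scenarios).
    """
    specs = standard_grid() if specs is None else list(specs)
    base = run_scenario(dataset, BASE_SCENARIO, params, config)
    rows = [
        {
            "analysis": BASE_SCENARIO.name,
            "palys_lost": base.palys_lost,
            "pct_change": 0.0,
            "gdp_lost_usd": base.gdp_lost,
            "per_person_usd": base.per_person_usd,
        }
    ]
    for spec in specs:
        if spec == BASE_SCENARIO:
            continue
        res = run_scenario(dataset, spec, params, config)
        rows.append(
            {
                "analysis": spec.name,
                "palys_lost": res.palys_lost,
                "pct_change": percent_change(base, res),
                "gdp_lost_usd": res.gdp_lost,
                "per_person_usd": res.per_person_usd,
            }
        )
    return pd.DataFrame(rows)
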