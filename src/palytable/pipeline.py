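"""End-to-end burden pipeline: inputs -> country/stratum/total results.

For each country and 5-year age band, a cohort of one person starts at the
band midpoint age and is followed to retirement under the country's
mortality schedule.  PALYs lost per person is the per-year loss fraction
times the discounted person-years; scaling by the band's case count and
valuing via the TPL formula gives the country's lifetime loss.  The
cross-sectional (one-year) loss uses the same formula over a single
undiscounted year.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import (
    EconProfile,
    ModelConfig,
    MortalitySchedule,
    PrevalenceRecord,
    ProductivityParams,
    ValidationError,
)
from .economics import BurdenResult, aggregate, annual_loss, lifetime_loss
from .lifetable import simulate_cohort
from .paly import palys, palys_lost, productivity_index

__all__ = ["Dataset", "country_burdens", "run_pipeline", "PipelineResult"]


@dataclass
class Dataset:
    """One complete model input: prevalence, economics, mortality."""

    prevalence: list[PrevalenceRecord]
    econ: list[EconProfile]
    mortality: list[MortalitySchedule]

    def __post_init__(self) -> None:
        self._econ_by_country = {p.country_id: p for p in self.econ}
        self._mort_by_country = {m.country_id: m for m in self.mortality}

    @property
    def countries(self) -> list[str]:
        return sorted({r.country_id for r in self.prevalence})

    def econ_for(self, country_id: str) -> EconProfile:
        try:
            return self._econ_by_country[country_id]
        except KeyError:
            raise ValidationError(
                f"no economic profile for country {country_id!r}"
            ) from None

    def mortality_for(self, country_id: str) -> MortalitySchedule:
        try:
            return self._mort_by_country[country_id]
        except KeyError:
            raise ValidationError(
                f"no mortality schedule for country {country_id!r}"
            ) from None

    def validate(self, config: ModelConfig | None = None) -> None:
        """Check cross-table consistency and age coverage."""
        config = config or ModelConfig()
        for country in self.countries:
            self.econ_for(country)
            sched = self.mortality_for(country)
            for rec in self.prevalence:
                if rec.country_id == country:
                    sched.require_coverage(
                        rec.age_group.midpoint, config.retirement_age - 1
                    )


def _band_palys(
    rec: PrevalenceRecord,
    schedule: MortalitySchedule,
    params: ProductivityParams,
    config: ModelConfig,
    case_bound: str,
) -> tuple[float, float, float, float]:
    """(cases, PALYs lost, affected PALYs, healthy PALYs) for one band."""
    cases = rec.bounded_cases(case_bound)
    traj = simulate_cohort(1.0, rec.age_group.midpoint, schedule, config)
    rate = config.discount_rate
    healthy_pp = palys(traj, productivity_index(params, affected=False), rate)
    lost_pp = palys_lost(traj, params, rate)
    return cases, cases * lost_pp, cases * (healthy_pp - lost_pp), cases * healthy_pp


def country_burdens(
    dataset: Dataset,
    params: ProductivityParams | None = None,
    config: ModelConfig | None = None,
    *,
    horizon: str = "lifetime",
    case_bound: str = "point",
) -> list[BurdenResult]:
    """Per-country burden results.

    horizon="lifetime" follows each cohort to retirement with
    discounting; horizon="annual" is the base-year cross-section (one
    undiscounted year, PALYs lost per person = loss fraction).
    """
    params = params or ProductivityParams()
    config = config or ModelConfig()
    if horizon not in ("lifetime", "annual"):
        raise ValueError(f"unknown horizon {horizon!r}")

    results = []
    for country in dataset.countries:
        econ = dataset.econ_for(country)
        sched = dataset.mortality_for(country)
        recs = [r for r in dataset.prevalence if r.country_id == country]
        income_group = recs[0].income_group

        total_cases = 0.0
        total_palys_lost = 0.0
        total_loss = 0.0
        for rec in recs:
            cases = rec.bounded_cases(case_bound)
            total_cases += cases
            if horizon == "annual":
                total_palys_lost += cases * params.loss_fraction
                total_loss += annual_loss(cases, econ, params)
            else:
                _, band_lost, _, _ = _band_palys(
                    rec, sched, params, config, case_bound
                )
                total_palys_lost += band_lost
                total_loss += lifetime_loss(
                    cases, econ, band_lost / cases if cases > 0 else 0.0
                )
        results.append(
            BurdenResult(
                scope="country",
                scope_id=country,
                cases=total_cases,
                palys_lost=total_palys_lost,
                gdp_lost=total_loss,
                per_person_usd=total_loss / total_cases if total_cases > 0 else 0.0,
                loss_gdp_pct=100.0 * total_loss / econ.gdp_total,
                gdp_total=econ.gdp_total,
                income_group=income_group,
            )
        )
    return results


@dataclass(frozen=True)
class PipelineResult:
    """Everything the reporting layer needs for one model run."""

    annual: dict[str, list[BurdenResult]]
    lifetime: dict[str, list[BurdenResult]]
    palys_healthy: float
    palys_affected: float

    @property
    def total_lifetime(self) -> BurdenResult:
        return self.lifetime["total"][0]

    @property
    def total_annual(self) -> BurdenResult:
        return self.annual["total"][0]


def run_pipeline(
    dataset: Dataset,
    params: ProductivityParams | None = None,
    config: ModelConfig | None = None,
    *,
    case_bound: str = "point",
) -> PipelineResult:
    """Full model run: country, income-group and total results for the
    annual cross-section and the lifetime simulation, plus cohort-level
    PALY totals for the affected and hypothetical unaffected cohorts."""
    params = params or ProductivityParams()
    config = config or ModelConfig()

    healthy = 0.0
    affected = 0.0
    for rec in dataset.prevalence:
        sched = dataset.mortality_for(rec.country_id)
        _, _, band_affected, band_healthy = _band_palys(
            rec, sched, params, config, case_bound
        )
        healthy += band_healthy
        affected += band_affected

    out: dict[str, dict[str, list[BurdenResult]]] = {}
    for horizon in ("annual", "lifetime"):
        countries = country_burdens(
            dataset, params, config, horizon=horizon, case_bound=case_bound
        )
        out[horizon] = {
            "country": countries,
            "income_group": aggregate(countries, by="income_group"),
            "total": aggregate(countries, by="total"),
        }
    return PipelineResult(
        annual=out["annual"],
        lifetime=out["lifetime"],
        palys_healthy=healthy,
        palys_affected=affected,
    )
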