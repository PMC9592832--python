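"""Synthetic LMIC-style input panels.

The generator emulates the statistical shape of the real inputs without
reproducing any real country: presbyopia case counts that rise with age
within the 40-64 working-age bands (prevalence times a synthetic band
population), Gompertz mortality q(a) = a0 * exp(b * (a - 40)) giving
realistic age-increasing death probabilities, and income-group-stratified
economies (GDP per capita ranges bracketing the World Bank income-class
thresholds, employment ratio never exceeding participation).  Uncertainty
bounds are simple symmetric envelopes cases * (1 -/+ ci_width) — no
attempt is made to mimic GBD's uncertainty-propagation machinery.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    AgeGroup,
    EconProfile,
    MortalitySchedule,
    PrevalenceRecord,
    ValidationError,
)
from .pipeline import Dataset

__all__ = ["SynthSpec", "gen_dataset", "gen_worked_fixture", "WORKED_FIXTURE_NOTE"]

#: working-age bands of the analysis
_BANDS = (40, 45, 50, 55, 60)

#: GDP-per-capita sampling ranges (current US$) per income stratum,
#: bracketing the 2019 World Bank classification thresholds.
_GDP_PC_RANGES = {
    "low": (500.0, 1_050.0),
    "lower_middle": (1_050.0, 4_100.0),
    "upper_middle": (4_100.0, 12_500.0),
}


@dataclass(frozen=True)
class SynthSpec:
    """Generator parameters; defaults are the standard study conditions.

    prevalence_base: fraction of the 40-44 band population affected.
    prevalence_slope: multiplicative increase in prevalence per 5-year
        band (>= 1: the condition is non-decreasing in age).
    gompertz_a / gompertz_b: baseline annual mortality at age 40 and
        log-increase per year of age.
    ci_width: relative half-width of the symmetric case bounds.
    income_mix: fractions of countries in the low / lower-middle /
        upper-middle strata (must sum to 1).
    """

    n_countries: int = 20
    seed: int = 0
    income_mix: tuple[float, float, float] = (0.3, 0.4, 0.3)
    prevalence_base: float = 0.20
    prevalence_slope: float = 1.15
    gompertz_a: float = 0.004
    gompertz_b: float = 0.085
    ci_width: float = 0.35

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValidationError("n_countries must be >= 1")
        if abs(sum(self.income_mix) - 1.0) > 1e-9 or any(
            f < 0 for f in self.income_mix
        ):
            raise ValidationError("income_mix must be non-negative and sum to 1")
        if not 0.0 < self.prevalence_base <= 1.0:
            raise ValidationError("prevalence_base must be in (0, 1]")
        if self.prevalence_slope < 1.0:
            raise ValidationError(
                "prevalence_slope must be >= 1 (prevalence non-decreasing in age)"
            )
        if not 0.0 < self.gompertz_a < 1.0 or self.gompertz_b < 0:
            raise ValidationError("invalid Gompertz parameters")
        if not 0.0 <= self.ci_width < 1.0:
            raise ValidationError("ci_width must be in [0, 1)")


def _income_groups(spec: SynthSpec) -> list[str]:
    """Deterministic stratum assignment matching income_mix proportions."""
    counts = [int(round(f * spec.n_countries)) for f in spec.income_mix]
    while sum(counts) < spec.n_countries:
        counts[1] += 1
    while sum(counts) > spec.n_countries:
        counts[counts.index(max(counts))] -= 1
    groups = (
        ["low"] * counts[0]
        + ["lower_middle"] * counts[1]
        + ["upper_middle"] * counts[2]
    )
    return groups


def gen_dataset(spec: SynthSpec | None = None) -> Dataset:
    """Generate a fully validated synthetic panel."""
    spec = spec or SynthSpec()
    rng = np.random.default_rng(spec.seed)
    groups = _income_groups(spec)

    prevalence: list[PrevalenceRecord] = []
    econ: list[EconProfile] = []
    mortality: list[MortalitySchedule] = []
    for i, group in enumerate(groups):
        country = f"SYN{i:03d}"

        # Band populations: log-normal around ~1 million persons per band,
        # thinning slightly with age as real pyramids do.
        base_pop = rng.lognormal(mean=np.log(1e6), sigma=0.8)
        band_thinning = 0.92
        for j, lower in enumerate(_BANDS):
            pop = base_pop * band_thinning**j
            prev = min(1.0, spec.prevalence_base * spec.prevalence_slope**j)
            cases = pop * prev
            prevalence.append(
                PrevalenceRecord(
                    country_id=country,
                    income_group=group,
                    age_group=AgeGroup.from_lower(lower),
                    cases=cases,
                    cases_lower=cases * (1.0 - spec.ci_width),
                    cases_upper=cases * (1.0 + spec.ci_width),
                )
            )

        lo, hi = _GDP_PC_RANGES[group]
        gdp_pc = rng.uniform(lo, hi)
        # Total population ~ 4x the working-age 40-64 block.
        total_pop = base_pop * sum(band_thinning**j for j in range(5)) * 4.0
        lpr = rng.uniform(0.55, 0.80)
        er = lpr * rng.uniform(0.85, 0.98)
        econ.append(
            EconProfile(
                country_id=country,
                gdp_per_capita=gdp_pc,
                gdp_total=gdp_pc * total_pop,
                employment_ratio=er,
                labor_participation=lpr,
            )
        )

        q = {
            age: min(
                1.0, spec.gompertz_a * float(np.exp(spec.gompertz_b * (age - 40)))
            )
            for age in range(40, 65)
        }
        mortality.append(MortalitySchedule(country_id=country, q=q))

    return Dataset(prevalence=prevalence, econ=econ, mortality=mortality)


WORKED_FIXTURE_NOTE = """\
Three countries (one per income stratum), two age bands each (55-59 and
60-64), flat annual mortality q = 0.005 over ages 55-64, defaults
elsewhere (presenteeism 0.109, discount 3%, retirement 65).  Cohorts
start at the band midpoints 57 (8 cycles) and 62 (3 cycles), so the
discounted person-years per person are closed-form geometric sums
sum_{t=0}^{T-1} (0.995 / 1.03)^t, and every downstream total is
hand-checkable.
"""


def gen_worked_fixture() -> Dataset:
    """Tiny fixed 3-country, 2-band dataset with hand-computable totals."""
    rows = [
        # country, group, gdp_pc, gdp_total, er, lpr, cases(55-59), cases(60-64)
        ("AAA", "low", 1_000.0, 5.0e9, 0.60, 0.65, 100_000.0, 50_000.0),
        ("BBB", "lower_middle", 3_000.0, 60.0e9, 0.62, 0.68, 200_000.0, 80_000.0),
        ("CCC", "upper_middle", 9_000.0, 500.0e9, 0.58, 0.63, 300_000.0, 150_000.0),
    ]
    prevalence = []
    econ = []
    mortality = []
    for country, group, gdp_pc, gdp_total, er, lpr, c55, c60 in rows:
        for lower, cases in ((55, c55), (60, c60)):
            prevalence.append(
                PrevalenceRecord(
                    country_id=country,
                    income_group=group,
                    age_group=AgeGroup.from_lower(lower),
                    cases=cases,
                    cases_lower=cases * 0.8,
                    cases_upper=cases * 1.25,
                )
            )
        econ.append(
            EconProfile(
                country_id=country,
                gdp_per_capita=gdp_pc,
                gdp_total=gdp_total,
                employment_ratio=er,
                labor_participation=lpr,
            )
        )
        mortality.append(
            MortalitySchedule(
                country_id=country, q={age: 0.005 for age in range(55, 65)}
            )
        )
    return Dataset(prevalence=prevalence, econ=econ, mortality=mortality)
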