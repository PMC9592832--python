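# Methods

## Model

The package implements a prevalence-based, deterministic life-table
model of productivity losses from a non-fatal chronic condition,
applied to uncorrected and under-corrected presbyopia in the 40–64
working-age population of low- and middle-income countries.

Each 5-year age band of each country is simulated as one cohort of
fractional persons starting at the band midpoint age (lower + 2) and
followed in annual cycles until the retirement age (default 65). In
cycle *t*, survivors live a full person-year and a fraction
*q(a₀ + t)* of them dies at year end. Years of life are weighted by a
productivity index: 1 for the hypothetical unaffected cohort,
`1 − presenteeism − absenteeism_days / workdays_per_year` for the
affected cohort. Because the condition carries no excess mortality,
both cohorts share one survivorship curve, and the PALY difference
collapses analytically to

    PALYs lost = (presenteeism + absenteeism fraction)
                 × Σₜ survivors(t) · (1 + r)^(−t).

This identity holds for *every* mortality schedule and discount rate;
the test suite asserts it to 1e-12 relative, and it is why the lifetime
PALY-loss fraction reported by the acceptance script is exactly the
presenteeism parameter.

Monetary valuation uses TPL = TC × ER × LPR × PALYs-lost-per-person ×
GDP(PC). Both the employment-to-population ratio and the labour-force
participation rate are multiplied, although ER already embeds
participation; the formula is implemented verbatim as printed in the
source analyses rather than "corrected", and this choice is flagged
here deliberately. If GDP per full-time worker is preferred as the
value of one PALY, supply it in the `gdp_per_capita` slot of the
economic profile; the formula is unchanged.

The cross-sectional ("annual") result is the same formula over a single
undiscounted year, with PALYs lost per person equal to the per-year
loss fraction.

## Parameters

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| presenteeism | 0.109 | fraction/year | pooled estimate of on-the-job productivity reduction from prior studies of uncorrected presbyopia |
| absenteeism_days | 0 | days/year | assumed zero for presbyopia; the pathway is implemented for reuse |
| workdays_per_year | 250 | days | converts absenteeism days to a fraction; standard 5-day working year |
| discount_rate | 0.03 | fraction/year | WHO-standard discounting of life-years and PALYs |
| retirement_age | 65 | years | simulation horizon |
| base_year | 2019 | — | calendar year of the cross-sectional inputs; current US$ of that year, no inflation or wage growth |

## Numerical and cohort conventions

Where the source presentation is silent, the package fixes these
conventions (they are declared choices, not inferences):

- **Annual cycles**, not 5-year cycles: a 5-year cycle cannot truncate
  exactly at age 65 for mid-band starters.
- **Deaths at year end**: decedents contribute a full person-year in
  their death year; no half-cycle correction. This keeps the
  loss-fraction identity exact.
- **Band midpoint start age**: the band [a, a+4] is simulated as one
  cohort starting at a+2 (unbiased central age).
- **Discounting** uses (1 + r)^(−t) with t = 0 in the base year, so the
  first simulated year is undiscounted.
- **Fractional persons** throughout — an expected-value life table, not
  a stochastic micro-simulation; results are exactly reproducible.
- Ratios are stored as fractions in [0, 1]; 5-year-band death
  probabilities q5 are converted to annual q via 1 − (1 − q5)^(1/5), so
  five annual cycles reproduce the band survival exactly.
- Rounding (2 decimals, billions/trillions scaling) happens only at the
  rendering boundary; results files keep full precision.
- `top_k_share` breaks ties in GDP lost lexicographically by country id
  so rankings are deterministic.

## Scenario engine

Deterministic one-way scenarios re-run the entire pipeline with one
input moved: case counts to their lower/upper uncertainty bounds,
presenteeism scaled by 0.75 / 1.25, or the discount rate set to 5 % or
1.5 %. Re-running the pipeline (rather than rescaling outputs) keeps
factor interactions representable while reproducing the one-at-a-time
grid exactly. Linearity in presenteeism makes the ±25 % scenarios move
total PALYs lost by exactly ∓/± 25 % on any dataset; the discount-rate
scenarios move PALYs lost in the expected directions, with
data-dependent magnitudes. Per-person figures in the scenario table use
each scenario's own case count.

## Synthetic data

The generator emulates the statistical structure of the real inputs —
it is a modelling substrate, not a statistical reconstruction of any
country. Defaults, chosen once as the standard study conditions:

- 20 countries, income mix 0.3 / 0.4 / 0.3 across the low,
  lower-middle and upper-middle strata;
- prevalence 0.20 in the 40–44 band rising ×1.15 per 5-year band
  (near-vision impairment rises steeply through the 40s and 50s);
- band populations log-normal around 10⁶ persons, thinning ×0.92 per
  band as real age pyramids do;
- Gompertz mortality q(a) = 0.004·exp(0.085·(a − 40)), i.e. adult
  mortality doubling roughly every 8 years, clipped to [0, 1];
- GDP per capita uniform within stratum ranges bracketing the 2019
  World Bank classification thresholds (≈$500–1 050, $1 050–4 100,
  $4 100–12 500); LPR uniform 0.55–0.80 with ER = LPR × U(0.85, 0.98)
  so the employed are always a subset of the active;
- symmetric case bounds cases × (1 ∓ 0.35), roughly the relative width
  of GBD-style uncertainty intervals.

What the generator does **not** reproduce: real cross-country
correlations (population size vs income vs mortality), asymmetric GBD
uncertainty propagation, calendar trends in mortality, or future
incidence. Passing tests on synthetic data therefore validate the
model's arithmetic, identities and code paths — not the empirical
magnitudes of any real-world burden, which depend entirely on the input
extracts supplied.

The worked fixture (3 countries, bands 55–59 and 60–64, flat q = 0.005)
is constructed so that every total is a closed-form geometric sum; the
expected values frozen in the tests were computed independently from
those sums.

## Problem sizes

The default test and acceptance runs use panels of 6–20 countries × 5
age bands (≤ 100 cohorts, ≤ 23 annual cycles each), which this
deterministic model computes in well under a second; larger panels
scale linearly.

## Known limitations

- Mortality is fixed over calendar time (the classical life-table
  assumption) and identical in both cohorts.
- A single pooled presenteeism applies to all ages, countries and
  income groups; no age- or task-specific weights.
- No future incidence: only the prevalent base-year cohort is followed,
  which understates losses in a growing condition.
- Uncertainty handling is limited to running the model at the printed
  lower/upper case bounds; there is no probabilistic sensitivity
  analysis.
- No currency conversion, PPP adjustment or friction-cost valuation.
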