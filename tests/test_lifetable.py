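"""Cohort life-table engine: survivorship, person-years, discounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palytable import (
    ModelConfig,
    MortalitySchedule,
    ValidationError,
    discount_factors,
    discounted_person_years,
    simulate_cohort,
)


def schedule(q_by_age):
    return MortalitySchedule(country_id="X", q=dict(q_by_age))


def flat_schedule(q, start=40, stop=65):
    return schedule({age: q for age in range(start, stop)})


def brute_force_dpy(initial, start_age, q_map, retirement, rate):
    """Independent oracle: survival recomputed from scratch for each year."""
    total = 0.0
    for t in range(retirement - start_age):
        alive = initial
        for s in range(t):
            alive *= 1.0 - q_map[start_age + s]
        total += alive / (1.0 + rate) ** t
    return total


class TestSimulateCohort:
    def test_zero_mortality_keeps_everyone(self):
        traj = simulate_cohort(1000.0, 60, flat_schedule(0.0), ModelConfig())
        assert np.all(traj.survivors == 1000.0)
        assert traj.total_person_years == 5000.0
        assert traj.total_deaths == 0.0

    def test_certain_death_at_first_year_end(self):
        traj = simulate_cohort(1000.0, 60, flat_schedule(1.0), ModelConfig())
        assert traj.person_years.tolist() == [1000.0, 0.0, 0.0, 0.0, 0.0]

    def test_hand_computed_survival_chain(self):
        sched = schedule({62: 0.01, 63: 0.02, 64: 0.03})
        traj = simulate_cohort(100.0, 62, sched, ModelConfig())
        assert traj.person_years == pytest.approx([100.0, 99.0, 97.02], rel=1e-12)

    def test_trajectory_length_is_years_to_retirement(self):
        traj = simulate_cohort(10.0, 42, flat_schedule(0.01), ModelConfig())
        assert traj.n_years == 65 - 42
        assert len(traj.survivors) == traj.n_years + 1

    def test_schedule_gap_rejected(self):
        sched = schedule({a: 0.01 for a in range(60, 65) if a != 63})
        with pytest.raises(ValidationError, match="63"):
            simulate_cohort(10.0, 60, sched, ModelConfig())

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(-1.0, 60, flat_schedule(0.0), ModelConfig())

    def test_start_at_or_after_retirement_rejected(self):
        with pytest.raises(ValidationError):
            simulate_cohort(1.0, 65, flat_schedule(0.0, 40, 70), ModelConfig())


class TestDiscountFactors:
    def test_zero_rate_is_all_ones(self):
        assert discount_factors(3, 0.0).tolist() == [1.0, 1.0, 1.0]

    def test_three_percent_factors(self):
        got = discount_factors(3, 0.03)
        assert got == pytest.approx([1.0, 1 / 1.03, 1 / 1.03**2], rel=1e-12)

    def test_single_year_is_undiscounted(self):
        assert discount_factors(1, 0.05).tolist() == [1.0]


class TestDiscountedPersonYears:
    def test_immortal_person_matches_annuity_due(self):
        traj = simulate_cohort(1.0, 62, flat_schedule(0.0), ModelConfig())
        got = discounted_person_years(traj, 0.03)
        assert got == pytest.approx(1 + 1 / 1.03 + 1 / 1.03**2, rel=1e-12)

    def test_zero_rate_recovers_undiscounted_total(self):
        traj = simulate_cohort(7.0, 50, flat_schedule(0.02), ModelConfig())
        assert discounted_person_years(traj, 0.0) == pytest.approx(
            traj.total_person_years, rel=1e-12
        )

    def test_brute_force_oracle_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            start = int(rng.integers(40, 64))
            q_map = {a: float(rng.uniform(0, 0.2)) for a in range(start, 65)}
            initial = float(rng.uniform(0.1, 1e4))
            rate = float(rng.uniform(0, 0.08))
            traj = simulate_cohort(initial, start, schedule(q_map), ModelConfig())
            expect = brute_force_dpy(initial, start, q_map, 65, rate)
            assert discounted_person_years(traj, rate) == pytest.approx(
                expect, rel=1e-9
            )

    def test_closed_form_annuity_due_with_no_mortality(self):
        r = 0.03
        for start in (40, 50, 62):
            T = 65 - start
            traj = simulate_cohort(1.0, start, flat_schedule(0.0), ModelConfig())
            annuity = (1 - (1 + r) ** -T) / (1 - 1 / (1 + r))
            assert discounted_person_years(traj, r) == pytest.approx(
                annuity, rel=1e-12
            )


class TestInvariants:
    @settings(max_examples=50, deadline=None)
    @given(
        start=st.integers(min_value=40, max_value=63),
        seed=st.integers(min_value=0, max_value=2**31 - 1),
    )
    def test_conservation_and_monotone_survivors(self, start, seed):
        rng = np.random.default_rng(seed)
        q_map = {a: float(rng.uniform(0, 0.5)) for a in range(start, 65)}
        traj = simulate_cohort(100.0, start, schedule(q_map), ModelConfig())
        assert np.all(np.diff(traj.survivors) <= 1e-12)
        assert np.all(traj.deaths >= -1e-12)
        assert traj.initial_count == pytest.approx(
            traj.survivors[-1] + traj.total_deaths, rel=1e-12
        )

    def test_raising_mortality_weakly_decreases_person_years(self):
        base = {a: 0.02 for a in range(50, 65)}
        traj0 = simulate_cohort(100.0, 50, schedule(base), ModelConfig())
        for bump_age in (50, 57, 64):
            bumped = {**base, bump_age: 0.10}
            traj1 = simulate_cohort(100.0, 50, schedule(bumped), ModelConfig())
            assert traj1.total_person_years <= traj0.total_person_years + 1e-12

    def test_discounted_person_years_strictly_decreasing_in_rate(self):
        traj = simulate_cohort(100.0, 55, flat_schedule(0.03), ModelConfig())
        values = [discounted_person_years(traj, r) for r in (0.0, 0.015, 0.03, 0.05)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_discounting_never_exceeds_undiscounted(self):
        traj = simulate_cohort(10.0, 45, flat_schedule(0.01), ModelConfig())
        assert np.all(traj.discounted_person_years <= traj.person_years + 1e-15)
        assert traj.discounted_person_years[0] == traj.person_years[0]


def test_trajectory_frame_export():
    traj = simulate_cohort(10.0, 62, flat_schedule(0.01, 62, 65), ModelConfig())
    df = traj.to_frame()
    assert list(df.columns) == [
        "year",
        "age",
        "survivors",
        "deaths",
        "person_years",
        "discounted_person_years",
    ]
    assert df["age"].tolist() == [62, 63, 64]
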