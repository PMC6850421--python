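"""Dose ledgers and the larval/adult exposure mortality operators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beescape.dose_response import curve_from_anchor, evaluate_mortality
from beescape.pollen import (
    DoseLedger,
    MortalityState,
    adult_daily_mortality,
    conditional_increment,
    larval_mortality_at_pupation,
)


def acute_curve():
    return curve_from_anchor("weibull", 2.6, 0.999, steepness=4.0, window_days=2,
                             endpoint="adult_acute")


def chronic_curve():
    return curve_from_anchor("weibull", 3.25, 0.5, steepness=3.0, window_days=10,
                             endpoint="adult_chronic")


class TestDoseLedger:
    @given(st.lists(st.floats(0, 10), min_size=1, max_size=40),
           st.integers(1, 12))
    @settings(max_examples=100, deadline=None)
    def test_window_sum_matches_brute_force(self, doses, k):
        ledger = DoseLedger()
        for d in doses:
            ledger.record(d)
        brute = sum(doses[max(0, len(doses) - k):])
        assert ledger.window_sum(k) == pytest.approx(brute, abs=1e-12)

    def test_window_shorter_history_padded_with_zeros(self):
        ledger = DoseLedger()
        ledger.record(3.0)
        assert ledger.window_sum(10) == pytest.approx(3.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            DoseLedger().record(-0.1)


class TestLarvalMortality:
    def larval_curve(self):
        return curve_from_anchor("loglogistic", 109.704, 0.5, steepness=2.0,
                                 window_days=6, endpoint="larval_chronic")

    def ledger_with(self, daily, days=6):
        ledger = DoseLedger()
        for _ in range(days):
            ledger.record(daily)
        return ledger

    def test_zero_dose_spares_everyone(self):
        survivors = larval_mortality_at_pupation(
            self.ledger_with(0.0), self.larval_curve(), 1000.0
        )
        assert survivors == 1000.0

    def test_lc50_dose_halves_the_cohort(self):
        """Six days summing to the LC50-equivalent dose kill exactly half."""
        survivors = larval_mortality_at_pupation(
            self.ledger_with(109.704 / 6), self.larval_curve(), 1000.0
        )
        assert survivors == pytest.approx(500.0, abs=1e-6)

    def test_dose_doubling_never_increases_survivors(self):
        curve = self.larval_curve()
        prev = 1000.0
        for daily in (5.0, 10.0, 20.0, 40.0, 80.0):
            s = larval_mortality_at_pupation(self.ledger_with(daily), curve, 1000.0)
            assert s <= prev + 1e-9
            prev = s

    def test_short_ledger_rejected(self):
        with pytest.raises(ValueError, match="development"):
            larval_mortality_at_pupation(self.ledger_with(1.0, days=3),
                                         self.larval_curve(), 100.0)

    def test_binomial_mode_matches_expectation(self, rng):
        curve = self.larval_curve()
        ledger = self.ledger_with(109.704 / 6)
        draws = [
            larval_mortality_at_pupation(ledger, curve, 1000.0, mode="binomial", rng=rng)
            for _ in range(200)
        ]
        assert np.mean(draws) == pytest.approx(500.0, abs=3 * 1000 * 0.5 / np.sqrt(200))


class TestAdultMortality:
    def run_schedule(self, daily_doses, count=1e5):
        """Apply the daily operator along a dose schedule (expected-value)."""
        acute, chronic = acute_curve(), chronic_curve()
        ledger = DoseLedger()
        state = MortalityState.fresh(acute, chronic)
        counts = [count]
        for d in daily_doses:
            ledger.record(d)
            count, state = adult_daily_mortality(ledger, acute, chronic, count, state)
            counts.append(count)
        return np.array(counts), state

    def test_zero_exposure_no_mortality(self):
        counts, _ = self.run_schedule([0.0] * 30)
        assert counts[-1] == counts[0]

    def test_cumulative_mortality_capped_by_window_maximum(self):
        """A single exposure day can never kill more than P(max window dose)."""
        acute, chronic = acute_curve(), chronic_curve()
        dose = 1.5
        counts, _ = self.run_schedule([dose] + [0.0] * 25)
        p_cap = 1.0 - (1.0 - evaluate_mortality(acute, dose)) * (
            1.0 - evaluate_mortality(chronic, dose)
        )
        applied = 1.0 - counts[-1] / counts[0]
        assert applied <= p_cap + 1e-12

    def test_constant_exposure_converges_to_curve_value(self):
        """Under steady dosing the total applied mortality equals the curve
        at the full-window dose (the conditional increments telescope)."""
        daily = 0.2
        counts, state = self.run_schedule([daily] * 40)
        acute, chronic = acute_curve(), chronic_curve()
        p_a = evaluate_mortality(acute, 2 * daily)
        p_c = evaluate_mortality(chronic, 10 * daily)
        expected = counts[0] * (1 - p_a) * (1 - p_c)
        assert counts[-1] == pytest.approx(expected, rel=1e-9)
        assert state.p_acute == pytest.approx(p_a)
        assert state.p_chronic == pytest.approx(p_c)

    def test_acute_lc100_wipes_cohort_within_a_day(self):
        """Sustained dietary 200 ng/g at the in-hive rate is acutely lethal."""
        daily = 200.0 * 6.5e-3  # ng/bee/day
        counts, _ = self.run_schedule([daily] * 3, count=1000.0)
        assert counts[-1] <= 0.01 * counts[0]

    def test_expected_value_matches_per_bee_monte_carlo(self, rng):
        """Cohort expected-value accounting agrees with a brute-force
        per-bee Bernoulli simulation of the same daily hazards."""
        schedule = [0.0, 0.4, 0.9, 0.0, 0.0, 0.3, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        n = 100_000
        counts, _ = self.run_schedule(schedule, count=float(n))

        acute, chronic = acute_curve(), chronic_curve()
        alive = np.ones(n, dtype=bool)
        ledger = DoseLedger()
        p_star_a, p_star_c = acute.background, chronic.background
        for d in schedule:
            ledger.record(d)
            p_a = evaluate_mortality(acute, ledger.window_sum(2))
            p_c = evaluate_mortality(chronic, ledger.window_sum(10))
            h_a = float(conditional_increment(p_a, p_star_a))
            h_c = float(conditional_increment(p_c, p_star_c))
            p_star_a, p_star_c = max(p_star_a, p_a), max(p_star_c, p_c)
            h = 1 - (1 - h_a) * (1 - h_c)
            if h > 0:
                alive &= rng.random(n) >= h
        expected_frac = counts[-1] / n
        mc_frac = alive.mean()
        se = np.sqrt(max(expected_frac * (1 - expected_frac), 1e-12) / n)
        assert abs(mc_frac - expected_frac) <= 3 * se


@given(st.lists(st.floats(0, 2.0), min_size=5, max_size=30))
@settings(max_examples=60, deadline=None)
def test_applied_mortality_never_exceeds_window_maximum(doses):
    """Property: per-endpoint cumulative applied mortality is bounded by the
    curve value at the largest window dose ever observed."""
    acute, chronic = acute_curve(), chronic_curve()
    ledger = DoseLedger()
    state = MortalityState.fresh(acute, chronic)
    count = 1.0
    max_a = max_c = 0.0
    for d in doses:
        ledger.record(d)
        count, state = adult_daily_mortality(ledger, acute, chronic, count, state)
        max_a = max(max_a, ledger.window_sum(2))
        max_c = max(max_c, ledger.window_sum(10))
    cap = 1.0 - (1.0 - evaluate_mortality(acute, max_a)) * (
        1.0 - evaluate_mortality(chronic, max_c)
    )
    assert 1.0 - count <= cap + 1e-9
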