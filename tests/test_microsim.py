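"""The continuous-time engine against its closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mdd_lifecourse as ml
from mdd_lifecourse.microsim import (
    MDD,
    cumulative_incidence_hazard,
    simulate_two_state,
)

from conftest import constant_rate_table

BANDS = ml.AgeBands.five_year()
S = ("female", 10)


class TestWaitingTime:
    def test_zero_hazard_is_always_censored(self):
        assert ml.sample_waiting_time(np.zeros(10), BANDS, 30.0, 0.5) is None

    def test_constant_hazard_closed_form(self):
        # lambda = 0.1 from age 20 with -ln(u) = 1 -> event at age 30
        t = ml.sample_waiting_time(np.full(10, 0.1), BANDS, 20.0, np.exp(-1.0))
        assert t == pytest.approx(30.0, abs=1e-9)

    def test_piecewise_integration_across_band_boundary(self):
        # hazard 0 on [18,23), 0.5 afterwards; -ln(u) = 1 from 18 -> age 25
        h = np.full(10, 0.5)
        h[0] = 0.0
        t = ml.sample_waiting_time(h, BANDS, 18.0, np.exp(-1.0))
        assert t == pytest.approx(25.0, abs=1e-9)

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.3, 1.7])
    def test_u_outside_unit_interval_rejected(self, u):
        with pytest.raises(ValueError):
            ml.sample_waiting_time(np.full(10, 0.1), BANDS, 30.0, u)

    def test_event_never_before_current_age(self):
        rng = np.random.default_rng(0)
        h = rng.uniform(0, 2.0, 10)
        for _ in range(200):
            age = float(rng.uniform(18, 64.9))
            t = ml.sample_waiting_time(h, BANDS, age, float(rng.uniform(1e-9, 1 - 1e-9)))
            assert t is None or age < t <= 65.0


class TestAnalyticOracle:
    def test_no_dynamics_keeps_initial_prevalence(self):
        table = constant_rate_table(0.0, 0.0, 0.17)
        for age in (18, 40, 65):
            assert ml.analytic_state_probability(table, S, age) == pytest.approx(0.17)

    def test_symmetric_rates_converge_to_half(self):
        table = constant_rate_table(2.0, 2.0, 0.0)
        assert ml.analytic_state_probability(table, S, 65.0) == pytest.approx(0.5, abs=1e-6)

    def test_constant_rates_closed_form(self):
        table = constant_rate_table(0.1, 0.4, 0.0)
        expected = 0.2 * (1 - np.exp(-5.0))  # p_eq (1 - e^{-(lam+mu) t}), t = 10
        assert ml.analytic_state_probability(table, S, 28.0) == pytest.approx(expected, rel=1e-12)

    def test_zero_total_rate_band_holds_probability_constant(self):
        inc = np.full(10, 0.2)
        rem = np.full(10, 0.3)
        inc[2] = rem[2] = 0.0
        table = ml.RateTable(BANDS, {S: inc}, {S: rem}, {S: 0.1})
        assert ml.analytic_state_probability(table, S, 33.0) == pytest.approx(
            ml.analytic_state_probability(table, S, 28.0)
        )


class TestSingleLifeCourse:
    def test_never_ill_without_initial_or_incident_disease(self):
        table = constant_rate_table(0.0, 0.5, 0.0)
        lc = ml.simulate_life_course(table, S, np.random.default_rng(1))
        assert lc.initial_state == "healthy"
        assert lc.transitions == []
        assert not lc.ever_mdd and lc.mdd_years == 0.0

    def test_chronic_course_when_no_remission(self):
        table = constant_rate_table(0.0, 0.0, 1.0)
        lc = ml.simulate_life_course(table, S, np.random.default_rng(1))
        assert lc.initial_state == MDD
        assert lc.mdd_years == pytest.approx(47.0)
        assert lc.onset_age is None  # prevalent at 18: onset undefined

    def test_transition_ages_increase_and_states_alternate(self):
        table = constant_rate_table(0.3, 0.5, 0.3)
        rng = np.random.default_rng(3)
        for i in range(50):
            lc = ml.simulate_life_course(table, S, rng, id=i)
            ages = [a for a, _ in lc.transitions]
            assert all(18 < a < 65 for a in ages)
            assert all(a < b for a, b in zip(ages, ages[1:]))
            states = [s for _, s in lc.transitions]
            expected_first = "mdd" if lc.initial_state == "healthy" else "healthy"
            for j, state in enumerate(states):
                assert state == (expected_first if j % 2 == 0 else
                                 ("healthy" if expected_first == "mdd" else "mdd"))

    def test_missing_stratum_rejected(self):
        table = constant_rate_table(0.1, 0.3, 0.0, strata=[("female", 10)])
        with pytest.raises(ml.SimulationError):
            ml.simulate_life_course(table, ("male", 16), np.random.default_rng(0))


class TestRunSimulation:
    def test_same_seed_reproduces_bit_identical_output(self):
        table = constant_rate_table(0.2, 0.4, 0.1)
        settings_ = ml.SimulationSettings(n_per_stratum=2000, seed=11)
        a = ml.run_simulation(table, settings_)
        b = ml.run_simulation(table, settings_)
        for s in a:
            np.testing.assert_array_equal(a[s].initial_mdd, b[s].initial_mdd)
            np.testing.assert_array_equal(
                np.nan_to_num(a[s].transition_ages), np.nan_to_num(b[s].transition_ages)
            )

    def test_one_course_per_stratum_shape(self):
        table = constant_rate_table(0.1, 0.3, 0.0)
        out = ml.run_simulation(table, ml.SimulationSettings(n_per_stratum=1, seed=0))
        assert len(out) == 4 and all(len(v) == 1 for v in out.values())

    def test_seed_to_seed_variation_is_within_monte_carlo_noise(self):
        table = constant_rate_table(0.02, 0.3, 0.03)
        prevs = []
        for seed in (1, 2):
            out = ml.run_simulation(table, ml.SimulationSettings(n_per_stratum=125_000, seed=seed))
            prevs.append(100 * out[S].ever_mdd.mean())
        assert abs(prevs[0] - prevs[1]) < 0.5  # percentage points at n = 125k

    def test_history_rates_identical_to_primary_change_nothing(self):
        table = constant_rate_table(0.15, 0.4, 0.2)
        settings_ = ml.SimulationSettings(n_per_stratum=5000, seed=4)
        plain = ml.run_simulation(table, settings_)
        switched = ml.run_simulation(table, settings_, history_rates=table)
        for s in plain:
            np.testing.assert_array_equal(
                np.nan_to_num(plain[s].transition_ages),
                np.nan_to_num(switched[s].transition_ages),
            )

    def test_history_rates_alter_course_after_first_remission_only(self):
        base = constant_rate_table(0.05, 0.5, 0.0)
        # after first remission, re-entry becomes impossible
        history = constant_rate_table(0.0, 0.5, 0.0)
        out = ml.run_simulation(base, ml.SimulationSettings(n_per_stratum=30_000, seed=6),
                                history_rates=history)
        for s, courses in out.items():
            # at most: onset, remission -- nothing after the first remission
            assert courses.n_transitions.max() <= 2

    def test_vectorised_engine_matches_scalar_reference_distribution(self):
        table = constant_rate_table(0.08, 0.35, 0.15)
        out = ml.run_simulation(table, ml.SimulationSettings(n_per_stratum=40_000, seed=2))
        rng = np.random.default_rng(99)
        scalar = [ml.simulate_life_course(table, S, rng) for _ in range(8000)]
        ever_vec = out[S].ever_mdd.mean()
        ever_sca = np.mean([lc.ever_mdd for lc in scalar])
        se = np.sqrt(ever_vec * (1 - ever_vec) * (1 / 40_000 + 1 / 8000))
        assert abs(ever_vec - ever_sca) < 4 * se
        dur_vec = out[S].mdd_years.mean()
        dur_sca = np.mean([lc.mdd_years for lc in scalar])
        se_d = np.std([lc.mdd_years for lc in scalar]) * np.sqrt(1 / 40_000 + 1 / 8000)
        assert abs(dur_vec - dur_sca) < 4 * se_d


class TestContainerStatistics:
    def make_courses(self):
        # two individuals: healthy->mdd(30)->healthy(33); mdd from 18 throughout
        ages = np.array([[30.0, 33.0], [np.nan, np.nan]])
        return ml.StratumLifeCourses(S, np.array([False, True]), ages)

    def test_hand_computed_durations_and_onsets(self):
        slc = self.make_courses()
        np.testing.assert_allclose(slc.mdd_years, [3.0, 47.0])
        np.testing.assert_allclose(slc.onset_age, [30.0, np.nan])
        np.testing.assert_array_equal(slc.ever_mdd, [True, True])
        np.testing.assert_array_equal(slc.state_at(31.0), [True, True])
        np.testing.assert_array_equal(slc.state_at(34.0), [False, True])

    def test_row_view_round_trips_through_lifecourse(self):
        slc = self.make_courses()
        lc = slc[0]
        assert lc.transitions == [(30.0, "mdd"), (33.0, "healthy")]
        assert lc.mdd_years == pytest.approx(3.0)
        assert slc.to_frame().shape[0] == 4  # 2 initial rows + 2 transitions


@settings(max_examples=10, deadline=None, derandomize=True)
@given(
    inc=st.lists(st.floats(0.002, 0.15), min_size=10, max_size=10),
    rem=st.lists(st.floats(0.05, 0.6), min_size=10, max_size=10),
    p18=st.floats(0.0, 0.3),
    seed=st.integers(0, 2**20),
)
def test_first_passage_and_duration_match_closed_forms(inc, rem, p18, seed):
    """Scalar oracles: P(ever MDD) and E[years in MDD] for arbitrary tables."""
    table = ml.RateTable(
        BANDS, {S: np.array(inc)}, {S: np.array(rem)}, {S: p18},
    )
    n = 60_000
    out = ml.run_simulation(table, ml.SimulationSettings(n, seed, strata=(S,)))[S]
    ever_expected = ml.first_passage_mdd_probability(table, S)
    se = np.sqrt(max(ever_expected * (1 - ever_expected), 1e-12) / n)
    assert abs(out.ever_mdd.mean() - ever_expected) <= 3 * se + 1e-9

    dur_expected = ml.expected_mdd_years(table, S)
    se_dur = out.mdd_years.std() / np.sqrt(n)
    assert abs(out.mdd_years.mean() - dur_expected) <= 3 * se_dur + 1e-9


def test_interval_simulation_matches_two_state_transition_matrix():
    """The generator's interval engine agrees with the closed-form P01/P10."""
    lam, mu, g = 0.12, 0.3, 2.5
    inc, rem = np.full(10, lam), np.full(10, mu)
    rng = np.random.Generator(np.random.Philox(key=42))
    n = 200_000
    start = np.full(n, 40.0)
    for init in (False, True):
        final, _ = simulate_two_state(
            inc, rem, BANDS, np.full(n, init), start, start + g, rng,
            record_transitions=False,
        )
        rho, pi = lam + mu, lam / (lam + mu)
        expected = pi + ((1 - pi) if init else -pi) * np.exp(-rho * g)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(final.mean() - expected) <= 3.5 * se


def test_cumulative_incidence_hazard_partial_band():
    table = constant_rate_table(0.1, 0.0, 0.0)
    assert cumulative_incidence_hazard(table, S, 20.5) == pytest.approx(0.25)
    assert cumulative_incidence_hazard(table, S) == pytest.approx(4.7)
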