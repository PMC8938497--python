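"""Vital-rate derivation, Euler stepping and scenario runs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frdpop import (
    PopulationState,
    ScenarioSpec,
    VitalRateParams,
    constant_schedule,
    density_factor,
    derive_rates,
    ramp_schedule,
    run_scenario,
    step,
)
from frdpop.dynamics import DerivedRates, simulate_paths


class TestDeriveRates:
    def test_mean_parameter_rates(self, mean_params):
        rates = derive_rates(mean_params)
        # independent evaluation of the finite-to-instantaneous transform
        B = 0.3125 * 1.0 * 2.3
        log_term = math.log(1 + (B - 0.23))
        assert rates.B == pytest.approx(0.71875, abs=1e-12)
        assert rates.A == pytest.approx((B / (B - 0.23)) * log_term, rel=1e-12)
        assert rates.D == pytest.approx((0.23 / (B - 0.23)) * log_term, rel=1e-12)
        assert rates.A == pytest.approx(0.5852, abs=1e-4)
        assert rates.D == pytest.approx(0.1873, abs=1e-4)
        assert rates.A > rates.D  # B > M

    def test_limit_at_b_equals_m(self):
        # fm*Q*Np chosen so B == M exactly
        params = VitalRateParams(Q=1.0, Np=0.23 / 0.3125, M=0.23)
        rates = derive_rates(params)
        assert rates.A == pytest.approx(rates.B, abs=1e-12)
        assert rates.D == pytest.approx(0.23, abs=1e-12)

    def test_continuity_near_limit(self):
        near = derive_rates(VitalRateParams(Q=1.0, Np=(0.23 + 1e-9) / 0.3125, M=0.23))
        at = derive_rates(VitalRateParams(Q=1.0, Np=0.23 / 0.3125, M=0.23))
        assert near.A == pytest.approx(at.A, abs=1e-6)
        assert near.D == pytest.approx(at.D, abs=1e-6)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            VitalRateParams(Q=0, Np=2.3, M=0.23)
        with pytest.raises(ValueError):
            VitalRateParams(Q=1, Np=2.3, M=1.2)


class TestDensityFactor:
    @pytest.mark.parametrize(
        "pop,K,expected",
        [
            (6781, 24200, 1 - 6781 / 24200),
            (24200, 24200, 0.0),
            (0, 24200, 1.0),
            (36300, 24200, 0.0),  # clamped above K
        ],
    )
    def test_values(self, pop, K, expected):
        assert density_factor(pop, K) == pytest.approx(expected, abs=1e-12)

    def test_bad_k(self):
        with pytest.raises(ValueError):
            density_factor(100, 0)


class TestStep:
    def test_hand_computed_euler_step(self, mean_rates, initial_state):
        """Independent arithmetic walk through every flow at the initial state."""
        A, D, fm = mean_rates.A, mean_rates.D, 0.3125
        pop = 6781.0
        kt = 1 - pop / 24200
        female = 5234 * fm
        male = 5234 - female
        bi = A * (male + female) * kt
        death1 = 1547 * D * kt
        death2 = 5234 * D * kt
        maturation = 1547.0
        expected_py = 1547 + bi - death1 - (maturation - death1)
        expected_ad = 5234 + (maturation - death1) - death2

        nxt, flows = step(initial_state, mean_rates, s=0.0, K=24200, dt=1.0)
        assert nxt.puppy_young == pytest.approx(expected_py, rel=1e-12)
        assert nxt.adult == pytest.approx(expected_ad, rel=1e-12)
        assert nxt.population == pytest.approx(8071.66, abs=0.5)
        assert flows.bi == pytest.approx(bi, rel=1e-12)
        assert flows.di == pytest.approx(death1 + death2, rel=1e-12)

    def test_at_carrying_capacity_only_maturation_moves(self, mean_rates):
        state = PopulationState(puppy_young=4200, adult=20000)  # pop == K
        nxt, flows = step(state, mean_rates, s=0.0, K=24200, dt=1.0)
        assert flows.kt == 0.0
        assert flows.bi == 0.0
        assert flows.death1 == 0.0 and flows.death2 == 0.0
        assert nxt.puppy_young == pytest.approx(0.0)
        assert nxt.adult == pytest.approx(24200.0)

    def test_full_sterilization_stops_births(self, mean_rates, initial_state):
        _, flows = step(initial_state, mean_rates, s=1.0, K=24200)
        assert flows.bi == 0.0

    @given(
        py=st.floats(0, 20000), ad=st.floats(0, 40000),
        s=st.floats(0, 1), K=st.floats(1000, 60000),
        A=st.floats(0.05, 1.2), D=st.floats(0.05, 0.9),
    )
    @settings(max_examples=300, derandomize=True)
    def test_flow_conservation(self, py, ad, s, K, A, D):
        """Stock increments sum to births minus total deaths (the net-flow
        identity of the aggregate population equation)."""
        rates = DerivedRates(B=A, A=A, D=D)
        state = PopulationState(py, ad)
        nxt, flows = step(state, rates, s=s, K=K, dt=1.0)
        d_py_raw = flows.bi - flows.death1 - (flows.maturation - flows.death1)
        d_ad_raw = (flows.maturation - flows.death1) - flows.death2
        clamped = (state.puppy_young + d_py_raw < 0) or (state.adult + d_ad_raw < 0)
        if not clamped:
            delta = (nxt.population - state.population)
            assert delta == pytest.approx(flows.bi - flows.di, rel=1e-9, abs=1e-9)
        assert nxt.puppy_young >= 0 and nxt.adult >= 0


class TestSchedules:
    def test_ramp_to_70_percent_over_5_years(self):
        assert ramp_schedule(0.7, 5) == pytest.approx([0.14, 0.28, 0.42, 0.56, 0.70])

    def test_zero_ramp(self):
        assert ramp_schedule(0.0, 5) == [0.0] * 5

    def test_single_year_ramp_equals_constant(self):
        assert ramp_schedule(0.7, 1) == pytest.approx([0.7])

    def test_bad_target(self):
        with pytest.raises(ValueError):
            ramp_schedule(1.5, 5)

    def test_constant(self):
        assert constant_schedule(0.3, 4) == [0.3] * 4


class TestRunScenario:
    def test_no_intervention_5_year_deterministic(self, mean_rates, initial_state):
        spec = ScenarioSpec(K=24200, spay_schedule=0.0, horizon=5,
                            initial_state=initial_state)
        traj = run_scenario(spec, mean_rates)
        assert traj.frame.loc[0, "population"] == pytest.approx(6781.0)
        assert traj.frame.loc[0, "fold_vs_baseline"] == pytest.approx(1.0)
        assert traj.final_population == pytest.approx(14015, rel=0.005)

    def test_50pct_5_year_deterministic(self, mean_rates, initial_state):
        spec = ScenarioSpec(K=24200, spay_schedule=0.5, horizon=5,
                            initial_state=initial_state)
        traj = run_scenario(spec, mean_rates)
        assert traj.final_population == pytest.approx(3823, rel=0.005)

    def test_zero_horizon_contains_only_initial_state(self, mean_rates, initial_state):
        spec = ScenarioSpec(K=24200, spay_schedule=0.0, horizon=0,
                            initial_state=initial_state)
        traj = run_scenario(spec, mean_rates)
        assert len(traj.frame) == 1
        assert traj.frame.loc[0, "population"] == pytest.approx(6781.0)

    def test_schedule_shorter_than_horizon_rejected(self, initial_state):
        with pytest.raises(ValueError, match="schedule"):
            ScenarioSpec(K=24200, spay_schedule=[0.1, 0.2], horizon=5,
                         initial_state=initial_state)

    def test_population_non_increasing_in_spay_rate(self, mean_rates, initial_state):
        pops = []
        for s in (0.0, 0.1, 0.3, 0.5, 0.6, 0.7):
            spec = ScenarioSpec(K=24200, spay_schedule=s, horizon=10,
                                initial_state=initial_state)
            pops.append(run_scenario(spec, mean_rates).frame["population"].to_numpy())
        for lower_s, higher_s in zip(pops, pops[1:]):
            assert np.all(higher_s <= lower_s + 1e-9)

    def test_population_non_decreasing_in_k_without_intervention(
        self, mean_rates, initial_state
    ):
        pops = []
        for K in (16592, 24200, 55000):
            spec = ScenarioSpec(K=K, spay_schedule=0.0, horizon=10,
                                initial_state=initial_state)
            pops.append(run_scenario(spec, mean_rates).frame["population"].to_numpy())
        for smaller_k, larger_k in zip(pops, pops[1:]):
            assert np.all(larger_k >= smaller_k - 1e-9)

    def test_never_grows_once_at_capacity(self, mean_rates):
        spec = ScenarioSpec(K=24200, spay_schedule=0.0, horizon=10,
                            initial_state=PopulationState(4200, 20000))
        traj = run_scenario(spec, mean_rates)
        pops = traj.frame["population"].to_numpy()
        assert np.all(np.diff(pops) <= 1e-9)
        assert np.all(pops <= 24200 + 1e-9)

    def test_monthly_step_close_to_annual(self, mean_rates, initial_state):
        annual = run_scenario(
            ScenarioSpec(K=24200, spay_schedule=0.0, horizon=5,
                         initial_state=initial_state, dt=1.0),
            mean_rates,
        )
        monthly = run_scenario(
            ScenarioSpec(K=24200, spay_schedule=0.0, horizon=5,
                         initial_state=initial_state, dt=1 / 12),
            mean_rates,
        )
        assert monthly.final_population == pytest.approx(
            annual.final_population, rel=0.15
        )

    def test_vectorised_paths_match_scalar_stepping(self, mean_rates, initial_state):
        spec = ScenarioSpec(K=24200, spay_schedule=0.3, horizon=10,
                            initial_state=initial_state)
        traj = run_scenario(spec, mean_rates)
        paths = simulate_paths(
            spec, np.array([mean_rates.A]), np.array([mean_rates.D]),
            fm=mean_rates.fm, du1=mean_rates.du1,
        )
        np.testing.assert_array_equal(paths[:, 0], traj.frame["population"].to_numpy())
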