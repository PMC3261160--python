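import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from renalcea import (Compartment, HealthState, Strategy, aggregate,
                      build_transition_row, dialysis_death_rate,
                      rate_to_annual_prob, run_cohort, run_microsim)
from renalcea.engine import TERMINATION_TOL
from renalcea.errors import ContractError, DomainError
from renalcea.synth import FixtureSpec, generate_parameter_set

from conftest import flat_params


class TestRateToProb:
    def test_zero_rate(self):
        assert rate_to_annual_prob(0.0) == 0.0

    def test_unit_conversion(self):
        assert rate_to_annual_prob(0.1) == pytest.approx(0.09516, abs=5e-6)

    def test_negative_rejected(self):
        with pytest.raises(DomainError):
            rate_to_annual_prob(-0.01)

    @given(st.floats(min_value=0, max_value=20))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_and_bounded(self, rate):
        # above ~ rate 20 the probability is 1 to machine precision
        p = rate_to_annual_prob(rate)
        assert 0 <= p < 1
        assert rate_to_annual_prob(rate + 0.1) > p


class TestDialysisDeathRate:
    def test_zero_exposure_reference_is_baseline(self):
        ps = flat_params(q_dial=1 - math.exp(-0.05))
        assert dialysis_death_rate(ps, 45, 0) == pytest.approx(0.05)

    def test_exponential_exposure_effect(self):
        ps = flat_params(q_dial=1 - math.exp(-0.05), gamma=0.08)
        assert dialysis_death_rate(ps, 45, 5) == pytest.approx(0.05 * math.exp(0.4))

    def test_linearity_in_hazard_ratio(self, default_params):
        from renalcea import Comorbidity
        ps = default_params.with_profile(comorbidity=Comorbidity.CARDIOVASCULAR)
        base = dialysis_death_rate(default_params, 50, 3)
        assert dialysis_death_rate(ps, 50, 3) == pytest.approx(base * 1.5)

    def test_age_below_support_rejected(self, default_params):
        with pytest.raises(DomainError):
            dialysis_death_rate(default_params, 10, 0)


LIVE_STATES = [
    HealthState(Compartment.WAITLIST_DIALYSIS, 3, 0),
    HealthState(Compartment.UNLISTED_DIALYSIS, 2, 0),
    HealthState(Compartment.FUNCTIONING_GRAFT, 4, 1),
    HealthState(Compartment.POST_GRAFT_DIALYSIS, 6, 3),
    HealthState(Compartment.CONSERVATIVE_CARE, 0, 0),
]


class TestTransitionRow:
    @pytest.mark.parametrize("state", LIVE_STATES)
    @pytest.mark.parametrize("strategy", list(Strategy))
    @pytest.mark.parametrize("cycle", [0, 5, 30])
    def test_rows_are_distributions(self, default_params, state, strategy, cycle):
        row = build_transition_row(state, default_params, strategy, cycle)
        assert abs(sum(row.values()) - 1.0) < 1e-12
        assert all(p >= 0 for p in row.values())

    def test_not_listing_never_transplants(self, default_params):
        for comp in (Compartment.WAITLIST_DIALYSIS, Compartment.UNLISTED_DIALYSIS):
            row = build_transition_row(HealthState(comp, 1, 0), default_params,
                                       Strategy.NOT_LISTING, 1)
            assert not any(s.compartment is Compartment.FUNCTIONING_GRAFT for s in row)

    def test_no_second_transplant(self, default_params):
        row = build_transition_row(HealthState(Compartment.POST_GRAFT_DIALYSIS, 5, 2),
                                   default_params, Strategy.LISTING, 6)
        assert not any(s.compartment is Compartment.FUNCTIONING_GRAFT for s in row)

    def test_clocks_advance_only_in_matching_compartment(self, default_params):
        row = build_transition_row(HealthState(Compartment.FUNCTIONING_GRAFT, 4, 1),
                                   default_params, Strategy.LISTING, 5)
        for succ in row:
            assert succ.dialysis_years == 4  # frozen while graft functions
            if succ.compartment is not Compartment.DEAD:
                assert succ.graft_years == 2

    def test_dead_has_no_transitions(self, default_params):
        with pytest.raises(ContractError):
            build_transition_row(HealthState(Compartment.DEAD), default_params,
                                 Strategy.LISTING, 0)


class TestRunCohort:
    def test_immortal_cohort_lives_to_the_horizon(self):
        ps = flat_params(q_dial=0.0, q_graft=0.0, max_age=100, age=45,
                         discount=0.0, half_cycle=False)
        res = aggregate(run_cohort(ps, Strategy.NOT_LISTING), ps)
        assert res.undiscounted_life_years == pytest.approx(55.0, abs=1e-9)

    def test_discounted_life_expectancy_matches_geometric_series(self):
        # Constant annual death probability, no transplant: the trace is a
        # geometric survival curve with a closed-form discounted sum.
        q, r, T = 0.2, 0.05, 55
        ps = flat_params(q_dial=q, discount=r, half_cycle=True, age=45, max_age=100)
        engine = aggregate(run_cohort(ps, Strategy.NOT_LISTING), ps).total_life_years
        v = 1 / (1 + r)
        closed = v ** 0.5 * (1 - ((1 - q) * v) ** T) / (1 - (1 - q) * v)
        assert engine == pytest.approx(closed, abs=1e-8)

    def test_zero_transplant_prob_makes_strategies_identical(self):
        ps = flat_params(q_dial=0.1, p_tx=0.0)
        a = run_cohort(ps, Strategy.LISTING)
        b = run_cohort(ps, Strategy.NOT_LISTING)
        assert np.array_equal(a.waitlist, b.waitlist)
        assert np.array_equal(a.dead, b.dead)
        assert a.graft.sum() == b.graft.sum() == 0.0

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("strategy", list(Strategy))
    def test_occupancy_conservation_and_monotone_death(self, seed, strategy):
        ps = generate_parameter_set(FixtureSpec(seed=seed))
        trace = run_cohort(ps, strategy)
        np.testing.assert_allclose(trace.occupancy_totals(), 1.0, atol=1e-10)
        assert np.all(np.diff(trace.dead) >= -1e-12)
        assert np.all(np.diff(trace.alive()) <= 1e-12)
        assert trace.dead[-1] >= 1 - TERMINATION_TOL

    def test_raising_hazards_weakly_reduces_life_years(self, default_params):
        from dataclasses import replace
        from renalcea import Comorbidity
        from renalcea.sensitivity import _set_hr

        ps = default_params.with_profile(comorbidity=Comorbidity.CARDIOVASCULAR)
        for strategy in Strategy:
            base_ly = aggregate(run_cohort(ps, strategy), ps).total_life_years
            worse_hr = _set_hr(ps, "dialysis", 2.5)
            assert aggregate(run_cohort(worse_hr, strategy), worse_hr).total_life_years < base_ly
            worse_gamma = replace(ps, trans=replace(ps.trans, dialysis_time_coefficient=0.3))
            assert (aggregate(run_cohort(worse_gamma, strategy), worse_gamma).total_life_years
                    < base_ly)


class TestMicrosim:
    def test_same_seed_is_reproducible(self, default_params):
        a = run_microsim(default_params, Strategy.LISTING, n=500, seed=11)
        b = run_microsim(default_params, Strategy.LISTING, n=500, seed=11)
        assert np.array_equal(a.compartment_occupancy()[0], b.compartment_occupancy()[0])
        assert np.array_equal(a.graft, b.graft)

    def test_certain_death_absorbs_in_one_cycle(self):
        ps = flat_params(q_dial=1.0)
        trace = run_microsim(ps, Strategy.NOT_LISTING, n=200, seed=3)
        assert trace.dead[1] == 1.0

    def test_occupancies_approach_cohort_trace(self, default_params):
        # Coarse check at modest n; the strict 3-SE criterion runs at n=10,000
        # in the acceptance suite.
        cohort = run_cohort(default_params, Strategy.LISTING)
        micro = run_microsim(default_params, Strategy.LISTING, n=2000, seed=29)
        occ_c, _ = cohort.compartment_occupancy()
        occ_m, _ = micro.compartment_occupancy()
        T = min(len(occ_c), len(occ_m))
        err = np.abs(occ_c[:T] - occ_m[:T]).max()
        assert err < 0.05
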