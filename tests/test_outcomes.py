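import numpy as np
import pytest

from renalcea import (Dominance, Strategy, StrategyResult, Verdict, aggregate,
                      compute_incremental, cumulative_incremental_series,
                      discount_factor, run_cohort, threshold_verdict)
from renalcea.engine import CohortTrace
from renalcea.errors import DomainError

from conftest import flat_params


def _result(ly, cost, label="x"):
    return StrategyResult(label, ly, cost, ly, cost)


class TestDiscountFactor:
    def test_zero_rate_is_unity(self):
        assert discount_factor(17, 0.0, True) == 1.0

    def test_half_cycle_weight_at_cycle_zero(self):
        assert discount_factor(0, 0.05, True) == pytest.approx(0.97590, abs=5e-6)

    def test_plain_weight_at_cycle_one(self):
        assert discount_factor(1, 0.05, False) == pytest.approx(0.95238, abs=5e-6)

    @pytest.mark.parametrize("rate", [-0.1, 1.0])
    def test_rate_domain(self, rate):
        with pytest.raises(DomainError):
            discount_factor(1, rate)


class TestAggregate:
    def _one_cycle_trace(self):
        return CohortTrace(Strategy.NOT_LISTING, 45,
                           waitlist=np.array([1.0, 0.0]),
                           graft=np.zeros((2, 3)), post_graft=np.zeros((2, 3)),
                           post_graft_new=np.zeros(2), conservative=np.zeros(2),
                           dead=np.array([0.0, 1.0]))

    def test_single_live_cycle_half_cycle_discounted(self):
        ps = flat_params(discount=0.05, half_cycle=True)
        res = aggregate(self._one_cycle_trace(), ps)
        assert res.total_life_years == pytest.approx(1.05 ** -0.5, abs=1e-9)

    def test_zero_costs_zero_total(self):
        ps = flat_params(dial_cost=0.0, tx_cost=0.0)
        assert aggregate(self._one_cycle_trace(), ps).total_cost == 0.0

    def test_cost_linearity(self, default_params):
        from renalcea.sensitivity import SWEEPABLE
        trace = run_cohort(default_params, Strategy.LISTING)
        base = aggregate(trace, default_params).total_cost
        k = 3.7
        scaled = default_params
        for name in ("dialysis_initial", "dialysis_maintenance",
                     "transplant_initial_uncomplicated", "transplant_initial_complicated",
                     "transplant_maintenance"):
            current = getattr(scaled.costs, name).mean
            scaled = SWEEPABLE[name](scaled, current * k)
        assert aggregate(trace, scaled).total_cost == pytest.approx(base * k, rel=1e-12)

    def test_discounting_reduces_totals(self, default_params):
        trace = run_cohort(default_params, Strategy.LISTING)
        res = aggregate(trace, default_params)
        assert res.total_life_years < res.undiscounted_life_years
        assert res.total_cost < res.undiscounted_cost


class TestIncremental:
    def test_northeast_tradeoff_carries_rounded_icer(self):
        incr = compute_incremental(_result(2.41, 28_269.0), _result(0.0, 0.0))
        assert incr.dominance is Dominance.TRADEOFF_NE
        assert incr.icer == 11_730

    def test_dominant_suppresses_icer(self):
        incr = compute_incremental(_result(3.84, -16_272.0), _result(0.0, 0.0))
        assert incr.dominance is Dominance.DOMINANT
        assert incr.icer is None

    def test_zero_cost_gain_is_dominant(self):
        incr = compute_incremental(_result(1.0, 0.0), _result(0.0, 0.0))
        assert incr.dominance is Dominance.DOMINANT
        assert incr.icer is None

    def test_zero_effect_is_undefined(self):
        incr = compute_incremental(_result(1.0, 10.0), _result(1.0, 5.0))
        assert incr.dominance is Dominance.UNDEFINED
        assert incr.icer is None

    def test_antisymmetry_mirrors_quadrants(self):
        a, b = _result(9.57, 504_908.0), _result(7.16, 476_639.0)
        fwd = compute_incremental(a, b)
        rev = compute_incremental(b, a)
        assert rev.delta_effect == -fwd.delta_effect
        assert rev.delta_cost == -fwd.delta_cost
        assert fwd.dominance is Dominance.TRADEOFF_NE
        assert rev.dominance is Dominance.TRADEOFF_SW


class TestCumulativeSeries:
    def test_identical_traces_give_zero_series(self):
        ps = flat_params(q_dial=0.1, p_tx=0.0)
        trace = run_cohort(ps, Strategy.NOT_LISTING)
        series = cumulative_incremental_series(trace, trace, ps)
        assert np.allclose(series.cum_delta_effect, 0.0)
        assert np.allclose(series.cum_delta_cost, 0.0)

    def test_final_element_matches_totals(self, default_params):
        listing = run_cohort(default_params, Strategy.LISTING)
        not_listing = run_cohort(default_params, Strategy.NOT_LISTING)
        incr = compute_incremental(aggregate(listing, default_params),
                                   aggregate(not_listing, default_params))
        series = cumulative_incremental_series(listing, not_listing, default_params)
        assert series.cum_delta_effect.iloc[-1] == pytest.approx(incr.delta_effect, abs=1e-10)
        assert series.cum_delta_cost.iloc[-1] == pytest.approx(incr.delta_cost, abs=1e-6)


class TestThresholdVerdict:
    def test_icer_below_threshold(self):
        incr = compute_incremental(_result(2.41, 28_269.0), _result(0.0, 0.0))
        assert threshold_verdict(incr, 50_000) is Verdict.COST_EFFECTIVE

    def test_icer_exactly_at_threshold_counts(self):
        incr = compute_incremental(_result(1.0, 50_000.0), _result(0.0, 0.0))
        assert threshold_verdict(incr, 50_000) is Verdict.COST_EFFECTIVE

    def test_dominant_passes_through(self):
        incr = compute_incremental(_result(1.0, -5.0), _result(0.0, 0.0))
        assert threshold_verdict(incr, 1) is Verdict.DOMINANT

    def test_undefined_warns_not_cost_effective(self):
        incr = compute_incremental(_result(1.0, 5.0), _result(1.0, 0.0))
        with pytest.warns(UserWarning):
            assert threshold_verdict(incr) is Verdict.NOT_COST_EFFECTIVE
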