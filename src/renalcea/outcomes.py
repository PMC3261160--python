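"""Discounting, reward accumulation, incremental comparison and ICER.

Life-years and costs are attached per annual cycle to a cohort trace and
discounted at the configured annual rate. With the half-cycle correction
switched on, each cycle's reward is weighted by the mid-cycle discount
factor (1+r)^-(t+0.5), the simplest convention consistent with treating
transitions as occurring mid-cycle. Conservative-care entrants contribute
half a life-year (they exit renal replacement therapy and die within the
year) at zero cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
import warnings

import numpy as np

from .engine import CohortTrace
from .errors import ContractError, DomainError
from .parameters import ParameterSet


def discount_factor(cycle, rate: float, half_cycle: bool = True):
    """Discount weight for a cycle: (1+rate)^-(cycle+0.5) under half-cycle
    correction, (1+rate)^-cycle otherwise."""
    if not 0 <= rate < 1:
        raise DomainError(f"discount rate must be in [0,1), got {rate}")
    cycle = np.asarray(cycle, dtype=float)
    if np.any(cycle < 0):
        raise DomainError("cycle must be >= 0")
    expo = cycle + 0.5 if half_cycle else cycle
    out = (1.0 + rate) ** -expo
    return float(out) if out.ndim == 0 else out


class Dominance(str, Enum):
    DOMINANT = "dominant"          # more effective, not more costly
    DOMINATED = "dominated"        # less effective, not less costly
    TRADEOFF_NE = "tradeoff_ne"    # more effective and more costly -> ICER
    TRADEOFF_SW = "tradeoff_sw"    # less effective and less costly
    UNDEFINED = "undefined"        # zero incremental effect


class Verdict(str, Enum):
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    DOMINANT = "dominant"
    DOMINATED = "dominated"


@dataclass
class StrategyResult:
    """Discounted and undiscounted totals for one strategy."""

    strategy: str
    total_life_years: float
    total_cost: float
    undiscounted_life_years: float
    undiscounted_cost: float
    life_years_per_cycle: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cost_per_cycle: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class IncrementalResult:
    """Listing-minus-not-listing increments, ICER and dominance class."""

    delta_effect: float
    delta_cost: float
    dominance: Dominance
    icer: int | None  # currency per life-year saved, round-half-up


def _cycle_costs(trace: CohortTrace, params: ParameterSet) -> np.ndarray:
    c = params.costs
    T = trace.n_cycles
    t_idx = np.arange(T)
    graft_total = trace.graft.sum(axis=1)
    pg_total = trace.post_graft.sum(axis=1)

    # dialysis: initial cost in the first year on dialysis (entry cohort at
    # cycle 0 and re-entrants after graft failure), maintenance thereafter
    dial_init_mass = np.where(t_idx == 0, trace.waitlist, 0.0) + trace.post_graft_new
    dial_maint_mass = np.where(t_idx == 0, 0.0, trace.waitlist) + pg_total - trace.post_graft_new

    # transplant: initial cost (complication-weighted) in the transplant year
    graft_new = np.array([trace.graft[t, t] if t < trace.graft.shape[1] else 0.0 for t in range(T)])
    p_comp = params.trans.perioperative_complication_prob
    tx_initial = (p_comp * c.transplant_initial_complicated.mean
                  + (1 - p_comp) * c.transplant_initial_uncomplicated.mean)
    graft_maint_mass = graft_total - graft_new

    addon_mass = trace.waitlist + graft_total + pg_total  # conservative care costs nothing
    return (c.dialysis_initial.mean * dial_init_mass
            + c.dialysis_maintenance.mean * dial_maint_mass
            + tx_initial * graft_new
            + c.transplant_maintenance.mean * graft_maint_mass
            + params.addon().mean * addon_mass)


def aggregate(trace: CohortTrace, params: ParameterSet) -> StrategyResult:
    """Accumulate discounted life-years and costs over a cohort trace.

    Life-years per cycle are the live occupancy at cycle start (conservative
    care weighted one half); costs are occupancy-weighted state costs.
    """
    T = trace.n_cycles
    ly = (trace.waitlist + trace.graft.sum(axis=1) + trace.post_graft.sum(axis=1)
          + 0.5 * trace.conservative)
    cost = _cycle_costs(trace, params)
    df = discount_factor(np.arange(T), params.config.discount_rate,
                         params.config.half_cycle_correction)
    return StrategyResult(
        strategy=trace.strategy.value,
        total_life_years=float(ly @ df),
        total_cost=float(cost @ df),
        undiscounted_life_years=float(ly.sum()),
        undiscounted_cost=float(cost.sum()),
        life_years_per_cycle=ly * df,
        cost_per_cycle=cost * df,
    )


def round_half_up(x: float) -> int:
    """Round to the nearest whole currency unit, halves away from zero-up."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def compute_incremental(listing: StrategyResult, not_listing: StrategyResult) -> IncrementalResult:
    """Incremental comparison of listing vs not listing.

    The ICER (delta cost / delta effect, rounded half-up to a whole currency
    unit) is reported only in the northeast trade-off quadrant. A strategy
    that gains life-years at zero or negative incremental cost is dominant;
    zero incremental effect leaves dominance undefined and the ICER absent.
    """
    de = listing.total_life_years - not_listing.total_life_years
    dc = listing.total_cost - not_listing.total_cost
    if de > 0 and dc > 0:
        dom, icer = Dominance.TRADEOFF_NE, round_half_up(dc / de)
    elif de > 0:
        dom, icer = Dominance.DOMINANT, None
    elif de < 0 and dc < 0:
        dom, icer = Dominance.TRADEOFF_SW, None
    elif de < 0:
        dom, icer = Dominance.DOMINATED, None
    else:
        dom, icer = Dominance.UNDEFINED, None
    return IncrementalResult(delta_effect=de, delta_cost=dc, dominance=dom, icer=icer)


def cumulative_incremental_series(listing: CohortTrace, not_listing: CohortTrace,
                                  params: ParameterSet):
    """Running discounted incremental life-years (and costs) by cycle.

    Traces of unequal (truncated) length are padded with all-dead cycles;
    the final element equals the totals of :func:`compute_incremental`.
    Returns a DataFrame with cycle, cum_delta_effect, cum_delta_cost.
    """
    import pandas as pd

    r_l = aggregate(listing, params)
    r_n = aggregate(not_listing, params)
    T = max(listing.n_cycles, not_listing.n_cycles)

    def pad(a):
        return np.pad(a, (0, T - len(a)))

    d_ly = pad(r_l.life_years_per_cycle) - pad(r_n.life_years_per_cycle)
    d_cost = pad(r_l.cost_per_cycle) - pad(r_n.cost_per_cycle)
    return pd.DataFrame({
        "cycle": np.arange(T),
        "cum_delta_effect": np.cumsum(d_ly),
        "cum_delta_cost": np.cumsum(d_cost),
    })


def threshold_verdict(incr: IncrementalResult, threshold: float = 50_000) -> Verdict:
    """Classify against a willingness-to-pay threshold per life-year saved.

    Dominant/dominated pass through; a northeast trade-off is cost-effective
    when its ICER is at or below the threshold. Undefined or southwest
    trade-offs are conservatively not cost-effective (with a warning for the
    undefined case).
    """
    if incr.dominance is Dominance.DOMINANT:
        return Verdict.DOMINANT
    if incr.dominance is Dominance.DOMINATED:
        return Verdict.DOMINATED
    if incr.dominance is Dominance.UNDEFINED:
        warnings.warn("zero incremental effect: verdict undefined, reported as not cost-effective")
        return Verdict.NOT_COST_EFFECTIVE
    if incr.dominance is Dominance.TRADEOFF_SW:
        return Verdict.NOT_COST_EFFECTIVE
    if incr.icer is None:  # pragma: no cover - NE always carries an ICER
        raise ContractError("northeast trade-off without an ICER")
    return Verdict.COST_EFFECTIVE if incr.icer <= threshold else Verdict.NOT_COST_EFFECTIVE
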