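"""Closed-cohort Markov engine with dialysis-exposure tunnel expansion.

Compartments: dialysis while waitlisted (or unlisted, under the non-listing
strategy), functioning graft, dialysis after graft failure, conservative
care (entrants who never start renal replacement therapy), and death.
Time-dependence is made Markov by expanding states with integer clocks:
cumulative years on dialysis (which drives the exponential time-on-dialysis
death-rate effect and pauses while the graft functions) and graft age
(which drives graft failure). All transplant recipients are transplanted
once; a failed graft returns the patient to dialysis until death.

Within a cycle, competing events are ordered: death first, then transplant
among survivors (listed dialysis only), then graft failure among surviving
recipients. Dialysis withdrawal is folded into the annual dialysis death
probability (withdrawal is counted as death in the concurrent year). State
membership is measured at cycle start; rewards are attached per cycle by the
outcomes module.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ConfigurationError, ContractError, DomainError
from .parameters import ParameterSet, band_for_age

TERMINATION_TOL = 1e-10
_MAX_OPEN_HORIZON = 1_000  # safety cap when max_age is disabled


class Strategy(str, Enum):
    LISTING = "listing"
    NOT_LISTING = "not_listing"


class Compartment(str, Enum):
    WAITLIST_DIALYSIS = "waitlist_dialysis"
    UNLISTED_DIALYSIS = "unlisted_dialysis"
    FUNCTIONING_GRAFT = "functioning_graft"
    POST_GRAFT_DIALYSIS = "post_graft_dialysis"
    CONSERVATIVE_CARE = "conservative_care"
    DEAD = "dead"


@dataclass(frozen=True)
class HealthState:
    """Expanded model state: compartment plus integer clocks.

    ``dialysis_years`` is cumulative completed years on dialysis (pre- and
    post-graft; paused while the graft functions); ``graft_years`` is
    completed years with the current graft. Clocks only advance while the
    matching compartment is occupied.
    """

    compartment: Compartment
    dialysis_years: int = 0
    graft_years: int = 0


def rate_to_annual_prob(rate):
    """Convert an annual event rate to an annual probability, 1 - exp(-rate)."""
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise DomainError("rate must be >= 0")
    out = -np.expm1(-rate)
    return float(out) if out.ndim == 0 else out


def dialysis_death_rate(params: ParameterSet, age: float, dialysis_years) -> float:
    """Annual death rate on dialysis before the withdrawal add-on.

    baseline_rate(age) * exp(gamma * dialysis_years) * HR(comorbidity).
    The exponential term captures the compounding risk of cardiac and
    non-cardiac death with total time spent on dialysis.
    """
    base = band_for_age(age, params.trans.baseline_dialysis_death_rate_by_age)
    gamma = params.trans.dialysis_time_coefficient
    hr = params.hr_dialysis().point
    out = base * np.exp(gamma * np.asarray(dialysis_years, dtype=float)) * hr
    return float(out) if out.ndim == 0 else out


def _at_horizon(params: ParameterSet, age: float) -> bool:
    # max_age is absorbing: the year ending at max_age is the last possible,
    # so death is forced in the cycle starting at max_age - 1.
    return params.config.max_age is not None and age >= params.config.max_age - 1


def _dialysis_death_prob(params: ParameterSet, age: float, dialysis_years):
    """Annual dialysis death probability incl. withdrawal, clipped to 1."""
    if _at_horizon(params, age):
        return np.ones_like(np.asarray(dialysis_years, dtype=float))
    q = rate_to_annual_prob(dialysis_death_rate(params, age, dialysis_years))
    return np.clip(q + params.trans.withdrawal_prob, 0.0, 1.0)


def _graft_death_prob(params: ParameterSet, age: float) -> float:
    if _at_horizon(params, age):
        return 1.0
    rate = band_for_age(age, params.trans.post_transplant_death_rate_by_age)
    return float(rate_to_annual_prob(rate * params.hr_graft().point))


def _graft_failure_prob(params: ParameterSet, graft_years):
    # Step function: each key applies from that graft age until the next key.
    table = params.trans.graft_failure_prob_by_graft_age
    keys = np.array(sorted(table))
    vals = np.array([table[k] for k in keys])
    k = np.asarray(graft_years, dtype=int)
    idx = np.clip(np.searchsorted(keys, k, side="right") - 1, 0, len(keys) - 1)
    out = vals[idx]
    return float(out) if out.ndim == 0 else out


def build_transition_row(state: HealthState, params: ParameterSet,
                         strategy: Strategy, cycle: int) -> dict[HealthState, float]:
    """One-cycle successor distribution for a live expanded state.

    The row sums to 1. Death competes first; transplant applies to surviving
    listed dialysis patients; graft failure applies to surviving recipients.
    The unlisted never reach a graft, and nobody is transplanted twice.
    """
    if state.compartment is Compartment.DEAD:
        raise ContractError("DEAD has no outgoing transitions")
    age = params.profile.age_at_listing + cycle
    d, k = state.dialysis_years, state.graft_years
    row: dict[HealthState, float] = {}

    if state.compartment in (Compartment.WAITLIST_DIALYSIS, Compartment.UNLISTED_DIALYSIS):
        q = float(_dialysis_death_prob(params, age, d))
        p_tx = (params.trans.transplant_prob()
                if (strategy is Strategy.LISTING
                    and state.compartment is Compartment.WAITLIST_DIALYSIS) else 0.0)
        row[HealthState(Compartment.DEAD, d, k)] = q
        surv = 1.0 - q
        if p_tx > 0:
            row[HealthState(Compartment.FUNCTIONING_GRAFT, d + 1, 0)] = surv * p_tx
        stay = surv * (1.0 - p_tx)
        if stay > 0 or not row:
            row[HealthState(state.compartment, d + 1, k)] = stay
    elif state.compartment is Compartment.FUNCTIONING_GRAFT:
        q = _graft_death_prob(params, age)
        pf = float(_graft_failure_prob(params, k))
        row[HealthState(Compartment.DEAD, d, k)] = q
        row[HealthState(Compartment.POST_GRAFT_DIALYSIS, d, k + 1)] = (1 - q) * pf
        row[HealthState(Compartment.FUNCTIONING_GRAFT, d, k + 1)] = (1 - q) * (1 - pf)
    elif state.compartment is Compartment.POST_GRAFT_DIALYSIS:
        q = float(_dialysis_death_prob(params, age, d))
        row[HealthState(Compartment.DEAD, d, k)] = q
        row[HealthState(Compartment.POST_GRAFT_DIALYSIS, d + 1, k)] = 1 - q
    elif state.compartment is Compartment.CONSERVATIVE_CARE:
        # Conservative-care entrants die during their first year.
        row[HealthState(Compartment.DEAD, d, k)] = 1.0
    else:  # pragma: no cover - enum is exhaustive
        raise ContractError(f"unhandled compartment {state.compartment}")
    return row


@dataclass
class CohortTrace:
    """Per-cycle state occupancancies of a closed cohort.

    Row ``t`` holds the occupancy measured at the start of cycle ``t``
    (age = start_age + t). ``graft[t, s]`` is the mass with a functioning
    graft whose first graft cycle was ``s`` (graft age ``t - s``, frozen
    dialysis exposure ``s``); ``post_graft[t, d]`` is the mass back on
    dialysis with cumulative exposure ``d``; ``post_graft_new[t]`` is the
    sub-mass that re-entered dialysis at ``t`` (charged the initial
    dialysis cost). The dialysis column for the waitlisted/unlisted
    compartment needs no tunnel: its exposure clock equals the cycle index.
    """

    strategy: Strategy
    start_age: int
    waitlist: np.ndarray        # (T,)
    graft: np.ndarray           # (T, S) by first graft cycle s
    post_graft: np.ndarray      # (T, D) by cumulative dialysis exposure d
    post_graft_new: np.ndarray  # (T,)
    conservative: np.ndarray    # (T,)
    dead: np.ndarray            # (T,)

    @property
    def n_cycles(self) -> int:
        return len(self.waitlist)

    def alive(self) -> np.ndarray:
        return (self.waitlist + self.graft.sum(axis=1)
                + self.post_graft.sum(axis=1) + self.conservative)

    def occupancy_totals(self) -> np.ndarray:
        return self.alive() + self.dead

    def compartment_occupancy(self):
        """(T, 5) array of occupancy by aggregate compartment, plus labels."""
        dial_label = (Compartment.WAITLIST_DIALYSIS if self.strategy is Strategy.LISTING
                      else Compartment.UNLISTED_DIALYSIS)
        cols = [dial_label, Compartment.FUNCTIONING_GRAFT, Compartment.POST_GRAFT_DIALYSIS,
                Compartment.CONSERVATIVE_CARE, Compartment.DEAD]
        arr = np.column_stack([self.waitlist, self.graft.sum(axis=1),
                               self.post_graft.sum(axis=1), self.conservative, self.dead])
        return arr, cols

    def to_frame(self):
        """Tidy export: cycle, age, compartment, occupancy, strategy."""
        import pandas as pd

        arr, cols = self.compartment_occupancy()
        rows = []
        for t in range(self.n_cycles):
            for j, comp in enumerate(cols):
                rows.append((t, self.start_age + t, comp.value, arr[t, j], self.strategy.value))
        return pd.DataFrame(rows, columns=["cycle", "age", "compartment", "occupancy", "strategy"])


def _horizon(params: ParameterSet) -> int:
    if params.config.max_age is not None:
        return params.config.max_age - params.profile.age_at_listing
    return _MAX_OPEN_HORIZON


def _truncate(trace: CohortTrace) -> CohortTrace:
    dead = trace.dead
    hit = np.nonzero(dead >= 1.0 - TERMINATION_TOL)[0]
    end = (hit[0] if len(hit) else len(dead) - 1) + 1
    return CohortTrace(trace.strategy, trace.start_age,
                       trace.waitlist[:end], trace.graft[:end], trace.post_graft[:end],
                       trace.post_graft_new[:end], trace.conservative[:end], trace.dead[:end])


def run_cohort(params: ParameterSet, strategy: Strategy) -> CohortTrace:
    """Deterministic expectation trace of a closed cohort.

    The cohort starts 100% in the strategy's dialysis compartment at
    age_at_listing with zero clocks, minus the conservative-care fraction,
    which occupies its own compartment for cycle 0 and is dead from cycle 1.
    The trace stops once the dead mass reaches 1 - 1e-10 or age reaches
    max_age (where death probability is forced to 1).
    """
    a0 = params.profile.age_at_listing
    T = _horizon(params)
    N = T + 2
    w = np.zeros(N)
    g = np.zeros((N, N + 1))
    pg = np.zeros((N, N + 1))
    pg_new = np.zeros(N)
    cons = np.zeros(N)
    dead = np.zeros(N)

    ccf = params.trans.conservative_care_fraction
    w[0] = 1.0 - ccf
    cons[0] = ccf
    p_tx = params.trans.transplant_prob() if strategy is Strategy.LISTING else 0.0

    d_idx = np.arange(N + 1)
    for t in range(N - 1):
        age = a0 + t
        deaths = cons[t]  # conservative care dies during its only year

        # waitlisted / unlisted dialysis (exposure clock = t)
        if w[t] > 0:
            q = float(_dialysis_death_prob(params, age, t))
            die = w[t] * q
            surv = w[t] - die
            tx = surv * p_tx
            g[t + 1, t + 1] += tx
            w[t + 1] = surv - tx
            deaths += die

        # functioning grafts, by first graft cycle s <= t
        row = g[t]
        if row.any():
            qg = _graft_death_prob(params, age)
            surv = row * (1.0 - qg)
            k = np.maximum(t - d_idx, 0)  # graft age per column
            pf = _graft_failure_prob(params, k)
            fail = surv * pf
            g[t + 1] += surv - fail
            pg[t + 1] += fail  # column s == cumulative exposure d
            pg_new[t + 1] = fail.sum()
            deaths += row.sum() * qg

        # post-graft dialysis, by cumulative exposure d
        prow = pg[t]
        if prow.any():
            q = _dialysis_death_prob(params, age, d_idx)
            die = prow * q
            surv = prow - die
            pg[t + 1, 1:] += surv[:-1]
            deaths += die.sum()

        dead[t + 1] = dead[t] + deaths
        if dead[t + 1] >= 1.0 - TERMINATION_TOL:
            end = t + 2
            trace = CohortTrace(strategy, a0, w[:end], g[:end], pg[:end],
                                pg_new[:end], cons[:end], dead[:end])
            return _truncate(trace)

    if params.config.max_age is None:
        raise ConfigurationError(
            "cohort did not die out within the open-horizon cap; "
            "set config.max_age or provide non-zero mortality")
    trace = CohortTrace(strategy, a0, w, g, pg, pg_new, cons, dead)
    return _truncate(trace)


def run_microsim(params: ParameterSet, strategy: Strategy,
                 n: int | None = None, seed: int | None = None) -> CohortTrace:
    """Individual-level simulation of ``n`` patients; converges to run_cohort.

    Each simulated patient carries its own compartment and clocks; event
    draws follow the same competing-event order as the cohort engine. The
    returned trace holds occupancy *proportions* (counts / n) in the same
    expanded-state layout as :func:`run_cohort`.
    """
    if n is None:
        n = params.config.cohort_size
    if n < 1:
        raise DomainError("n must be >= 1")
    if seed is None:
        seed = params.config.rng_seed
    rng = np.random.default_rng(seed)

    a0 = params.profile.age_at_listing
    T = _horizon(params)
    N = T + 2
    w = np.zeros(N)
    g = np.zeros((N, N + 1))
    pg = np.zeros((N, N + 1))
    pg_new = np.zeros(N)
    cons = np.zeros(N)
    dead = np.zeros(N)

    DIAL, GRAFT, PGD, CONS, DEADC = 0, 1, 2, 3, 4
    comp = np.full(n, DIAL, dtype=np.int64)
    comp[rng.random(n) < params.trans.conservative_care_fraction] = CONS
    expo = np.zeros(n, dtype=np.int64)      # cumulative dialysis years
    graft_s = np.zeros(n, dtype=np.int64)   # first graft cycle
    graft_k = np.zeros(n, dtype=np.int64)   # graft age
    entered_pg = np.zeros(n, dtype=np.int64)  # cycle of return to dialysis
    p_tx = params.trans.transplant_prob() if strategy is Strategy.LISTING else 0.0

    for t in range(N - 1):
        # record occupancy at cycle start
        w[t] = np.count_nonzero(comp == DIAL) / n
        cons[t] = np.count_nonzero(comp == CONS) / n
        dead[t] = np.count_nonzero(comp == DEADC) / n
        on_graft = comp == GRAFT
        if on_graft.any():
            g[t] += np.bincount(graft_s[on_graft], minlength=N + 1) / n
        on_pg = comp == PGD
        if on_pg.any():
            pg[t] += np.bincount(expo[on_pg], minlength=N + 1) / n
            pg_new[t] = np.count_nonzero(entered_pg[on_pg] == t) / n
        if dead[t] >= 1.0 - TERMINATION_TOL:
            end = t + 1
            return _truncate(CohortTrace(strategy, a0, w[:end], g[:end], pg[:end],
                                         pg_new[:end], cons[:end], dead[:end]))

        age = a0 + t
        u_death = rng.random(n)
        u_event = rng.random(n)

        dial = comp == DIAL
        if dial.any():
            q = _dialysis_death_prob(params, age, expo[dial])
            died = u_death[dial] < q
            idx = np.nonzero(dial)[0]
            comp[idx[died]] = DEADC
            alive_idx = idx[~died]
            expo[alive_idx] += 1
            if p_tx > 0 and alive_idx.size:
                tx = u_event[alive_idx] < p_tx
                tx_idx = alive_idx[tx]
                comp[tx_idx] = GRAFT
                graft_s[tx_idx] = t + 1
                graft_k[tx_idx] = 0

        if on_graft.any():
            qg = _graft_death_prob(params, age)
            idx = np.nonzero(on_graft)[0]
            died = u_death[idx] < qg
            comp[idx[died]] = DEADC
            alive_idx = idx[~died]
            if alive_idx.size:
                pf = _graft_failure_prob(params, graft_k[alive_idx])
                failed = u_event[alive_idx] < pf
                graft_k[alive_idx] += 1
                f_idx = alive_idx[failed]
                comp[f_idx] = PGD
                entered_pg[f_idx] = t + 1

        if on_pg.any():
            idx = np.nonzero(on_pg)[0]
            q = _dialysis_death_prob(params, age, expo[idx])
            died = u_death[idx] < q
            comp[idx[died]] = DEADC
            expo[idx[~died]] += 1

        comp[comp == CONS] = DEADC

    w[N - 1] = np.count_nonzero(comp == DIAL) / n
    dead[N - 1] = np.count_nonzero(comp == DEADC) / n
    if params.config.max_age is None and dead[N - 1] < 1.0 - TERMINATION_TOL:
        raise ConfigurationError("microsimulation did not terminate within the open-horizon cap")
    return _truncate(CohortTrace(strategy, a0, w, g, pg, pg_new, cons, dead))
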