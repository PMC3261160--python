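"""One-way (tornado) and probabilistic sensitivity analysis.

The PSA assigns a lognormal distribution to each relative risk (anchored at
the point estimate as the median, with the log-scale SD implied by the 95%
CI) and a moment-matched gamma distribution to each cost (shape (mean/se)^2,
scale se^2/mean). Each iteration draws every uncertain parameter, re-runs
both strategies through the cohort engine and records the incremental
effect and cost; iterations use independent RNG streams spawned from one
seed sequence, so results do not depend on parameter enumeration order.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import Strategy, run_cohort
from .errors import DomainError
from .outcomes import IncrementalResult, aggregate, compute_incremental, round_half_up
from .parameters import (Comorbidity, CostItem, HazardRatio, HazardRatioSet,
                         ParameterSet)


def sample_hr(point: float, ci95: tuple[float, float], rng: np.random.Generator) -> float:
    """Draw a hazard ratio from a lognormal anchored at the point as median."""
    lo, hi = ci95
    if not (0 < lo <= point <= hi):
        raise DomainError(f"require 0 < ci_low <= point <= ci_high, got {point}, [{lo}, {hi}]")
    sdlog = (np.log(hi) - np.log(lo)) / (2 * 1.96)
    if sdlog == 0:
        return float(point)
    return float(rng.lognormal(mean=np.log(point), sigma=sdlog))


def sample_cost(mean: float, se: float, rng: np.random.Generator) -> float:
    """Draw a cost from a moment-matched gamma (shape (mean/se)^2, scale se^2/mean)."""
    if se < 0:
        raise DomainError("se must be >= 0")
    if se == 0:
        return float(mean)
    if mean <= 0:
        raise DomainError("mean must be > 0 when se > 0")
    shape = (mean / se) ** 2
    scale = se ** 2 / mean
    return float(rng.gamma(shape, scale))


@dataclass
class PSASample:
    iteration: int
    hr_dialysis: float
    hr_graft: float
    costs: dict
    delta_effect: float
    delta_cost: float


@dataclass
class PSAResult:
    """Per-iteration incremental scatter plus summary statistics."""

    samples: list[PSASample]
    seed: int
    n_iter: int
    mean_delta_effect: float
    sd_delta_effect: float
    mean_delta_cost: float
    sd_delta_cost: float
    quadrant_proportions: dict  # NE / SE / NW / SW shares of the CE plane

    def scatter(self) -> pd.DataFrame:
        rows = [(s.iteration, s.delta_effect, s.delta_cost,
                 _quadrant(s.delta_effect, s.delta_cost)) for s in self.samples]
        return pd.DataFrame(rows, columns=["iteration", "delta_effect", "delta_cost", "quadrant"])


def _quadrant(de: float, dc: float) -> str:
    # Sign ties resolved toward the effect-favourable half-plane: a zero
    # incremental cost with a gain counts as SE (cost-saving side).
    if de > 0:
        return "NE" if dc > 0 else "SE"
    return "NW" if dc > 0 else "SW"


def _perturbed(params: ParameterSet, rng: np.random.Generator) -> tuple[ParameterSet, dict, float, float]:
    com = params.profile.comorbidity
    hr_d = params.hr_dialysis()
    hr_g = params.hr_graft()
    new_hr_d = sample_hr(hr_d.point, (hr_d.ci_low, hr_d.ci_high), rng)
    new_hr_g = sample_hr(hr_g.point, (hr_g.ci_low, hr_g.ci_high), rng)

    c = params.costs
    drawn = {
        "dialysis_initial": sample_cost(c.dialysis_initial.mean, c.dialysis_initial.se, rng),
        "dialysis_maintenance": sample_cost(c.dialysis_maintenance.mean, c.dialysis_maintenance.se, rng),
        "transplant_initial_uncomplicated": sample_cost(
            c.transplant_initial_uncomplicated.mean, c.transplant_initial_uncomplicated.se, rng),
        "transplant_initial_complicated": sample_cost(
            c.transplant_initial_complicated.mean, c.transplant_initial_complicated.se, rng),
        "transplant_maintenance": sample_cost(
            c.transplant_maintenance.mean, c.transplant_maintenance.se, rng),
        "comorbidity_annual_addon": sample_cost(params.addon().mean, params.addon().se, rng),
    }

    def _pt(v):  # degenerate point HR around a drawn value
        return HazardRatio(v, v, v)

    hr_set = HazardRatioSet(
        dialysis={**params.hr.dialysis, com: _pt(new_hr_d)},
        graft={**params.hr.graft, com: _pt(new_hr_g)},
    )
    if com is Comorbidity.NONE:  # reference HR stays exactly 1
        hr_set = params.hr

    addons = {**c.comorbidity_annual_addon, com: CostItem(drawn["comorbidity_annual_addon"], 0.0)}
    costs = replace(
        c,
        dialysis_initial=CostItem(drawn["dialysis_initial"], 0.0),
        dialysis_maintenance=CostItem(drawn["dialysis_maintenance"], 0.0),
        transplant_initial_uncomplicated=CostItem(drawn["transplant_initial_uncomplicated"], 0.0),
        transplant_initial_complicated=CostItem(drawn["transplant_initial_complicated"], 0.0),
        transplant_maintenance=CostItem(drawn["transplant_maintenance"], 0.0),
        comorbidity_annual_addon=addons,
    )
    return replace(params, hr=hr_set, costs=costs), drawn, new_hr_d, new_hr_g


def _increment(params: ParameterSet) -> IncrementalResult:
    listing = aggregate(run_cohort(params, Strategy.LISTING), params)
    not_listing = aggregate(run_cohort(params, Strategy.NOT_LISTING), params)
    return compute_incremental(listing, not_listing)


def run_psa(params: ParameterSet, n_iter: int | None = None,
            seed: int | None = None) -> PSAResult:
    """Monte-Carlo propagation of parameter uncertainty to (dE, dC)."""
    if n_iter is None:
        n_iter = params.config.psa_iterations
    if seed is None:
        seed = params.config.rng_seed
    children = np.random.SeedSequence(seed).spawn(n_iter)

    samples: list[PSASample] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        perturbed, drawn, hd, hg = _perturbed(params, rng)
        incr = _increment(perturbed)
        samples.append(PSASample(i, hd, hg, drawn, incr.delta_effect, incr.delta_cost))

    de = np.array([s.delta_effect for s in samples])
    dc = np.array([s.delta_cost for s in samples])
    quads = pd.Series([_quadrant(e, c) for e, c in zip(de, dc)])
    props = {q: float((quads == q).mean()) for q in ("NE", "SE", "NW", "SW")}
    return PSAResult(
        samples=samples, seed=seed, n_iter=n_iter,
        mean_delta_effect=float(de.mean()), sd_delta_effect=float(de.std(ddof=1)) if n_iter > 1 else 0.0,
        mean_delta_cost=float(dc.mean()), sd_delta_cost=float(dc.std(ddof=1)) if n_iter > 1 else 0.0,
        quadrant_proportions=props,
    )


# ---------------------------------------------------------------------------
# One-way sweeps
# ---------------------------------------------------------------------------

def _set_cost(params: ParameterSet, name: str, v: float) -> ParameterSet:
    return replace(params, costs=replace(params.costs, **{name: CostItem(v, getattr(params.costs, name).se)}))


def _set_trans(params: ParameterSet, name: str, v: float) -> ParameterSet:
    extra = {"annual_transplant_prob": None} if name == "median_wait" else {}
    return replace(params, trans=replace(params.trans, **{name: v}, **extra))


def _set_hr(params: ParameterSet, arm: str, v: float) -> ParameterSet:
    com = params.profile.comorbidity
    table = dict(getattr(params.hr, arm))
    table[com] = HazardRatio(v, v, v)
    return replace(params, hr=replace(params.hr, **{arm: table}))


def _set_addon(params: ParameterSet, v: float) -> ParameterSet:
    com = params.profile.comorbidity
    addons = {**params.costs.comorbidity_annual_addon, com: CostItem(v, params.addon().se)}
    return replace(params, costs=replace(params.costs, comorbidity_annual_addon=addons))


SWEEPABLE = {
    "median_wait": lambda p, v: _set_trans(p, "median_wait", v),
    "dialysis_time_coefficient": lambda p, v: _set_trans(p, "dialysis_time_coefficient", v),
    "withdrawal_prob": lambda p, v: _set_trans(p, "withdrawal_prob", v),
    "conservative_care_fraction": lambda p, v: _set_trans(p, "conservative_care_fraction", v),
    "perioperative_complication_prob": lambda p, v: _set_trans(p, "perioperative_complication_prob", v),
    "annual_transplant_prob": lambda p, v: _set_trans(p, "annual_transplant_prob", v),
    "discount_rate": lambda p, v: replace(p, config=replace(p.config, discount_rate=v)),
    "hr_dialysis": lambda p, v: _set_hr(p, "dialysis", v),
    "hr_graft": lambda p, v: _set_hr(p, "graft", v),
    "dialysis_initial": lambda p, v: _set_cost(p, "dialysis_initial", v),
    "dialysis_maintenance": lambda p, v: _set_cost(p, "dialysis_maintenance", v),
    "transplant_initial_uncomplicated": lambda p, v: _set_cost(p, "transplant_initial_uncomplicated", v),
    "transplant_initial_complicated": lambda p, v: _set_cost(p, "transplant_initial_complicated", v),
    "transplant_maintenance": lambda p, v: _set_cost(p, "transplant_maintenance", v),
    "comorbidity_annual_addon": lambda p, v: _set_addon(p, v),
}


@dataclass
class OneWayResult:
    """Grid evaluation of one parameter, all else at base case."""

    param: str
    entries: pd.DataFrame  # value, delta_effect, delta_cost, icer
    effect_range: float
    cost_range: float


def one_way_sweep(params: ParameterSet, param_id: str, low: float, high: float,
                  steps: int = 11) -> OneWayResult:
    """Evaluate incremental outcomes over a grid of one scalar parameter."""
    if param_id not in SWEEPABLE:
        raise KeyError(f"unknown sweepable parameter '{param_id}' "
                       f"(choose from {sorted(SWEEPABLE)})")
    if low > high:
        raise DomainError("low must be <= high")
    values = np.linspace(low, high, 1 if low == high else steps)
    rows = []
    for v in values:
        incr = _increment(SWEEPABLE[param_id](params, float(v)))
        rows.append((float(v), incr.delta_effect, incr.delta_cost,
                     incr.icer, incr.dominance.value))
    df = pd.DataFrame(rows, columns=["value", "delta_effect", "delta_cost", "icer", "dominance"])
    return OneWayResult(param_id, df,
                        effect_range=float(df.delta_effect.max() - df.delta_effect.min()),
                        cost_range=float(df.delta_cost.max() - df.delta_cost.min()))


def tornado(params: ParameterSet, ranges: dict[str, tuple[float, float]],
            steps: int = 2) -> pd.DataFrame:
    """Run one-way sweeps for several parameters, ordered by effect range."""
    results = [one_way_sweep(params, pid, lo, hi, steps) for pid, (lo, hi) in ranges.items()]
    results.sort(key=lambda r: r.effect_range, reverse=True)
    rows = [(r.param, r.entries.delta_effect.iloc[0], r.entries.delta_effect.iloc[-1],
             r.entries.delta_cost.iloc[0], r.entries.delta_cost.iloc[-1],
             r.effect_range, r.cost_range) for r in results]
    return pd.DataFrame(rows, columns=["param", "effect_low", "effect_high",
                                       "cost_low", "cost_high", "effect_range", "cost_range"])
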