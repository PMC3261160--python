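"""Seeded synthetic parameter sets with registry-like statistical structure.

Real clinical and cost inputs for a model of this kind come from renal
registries (age-specific waitlist and post-transplant mortality, adjusted
co-morbidity hazard ratios from Cox models, annual transplant and graft
failure probabilities) and national cost schedules. Those sources are not
bundled here; instead this module generates parameter sets that emulate
their structure: baseline dialysis mortality rising with age in a
two-parameter Gompertz shape, hazard ratios with lognormal-consistent
confidence intervals, and positive costs with standard errors.

``default_fixture`` loads the packaged, hand-calibrated parameter set used
throughout the tests and examples. It is calibration, not ground truth: it
is tuned to reproduce qualitative orderings (listing dominates for the
youngest profile, incremental life-years fall with age at listing, the
cumulative incremental-benefit curve crosses zero between years 4 and 6),
never absolute published values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import DomainError
from .parameters import (AGE_BAND_START, AGE_BAND_WIDTH, Comorbidity,
                         ComorbidityProfile, CostItem, CostSet, HazardRatio,
                         HazardRatioSet, ModelConfig, ParameterSet,
                         TransitionInputs, from_dict, UNIT_HR)
import yaml

_COMORBIDITIES = [Comorbidity.CARDIOVASCULAR, Comorbidity.DIABETES, Comorbidity.STROKE,
                  Comorbidity.OBESITY, Comorbidity.SMOKER]


def _default_ranges() -> dict:
    return {
        # Gompertz baseline: rate(age) = intercept * exp(slope * (age - 20))
        "gompertz_intercept": (0.015, 0.030),
        "gompertz_slope": (0.035, 0.050),
        # post-transplant mortality relative to the zero-exposure dialysis baseline
        "post_transplant_ratio": (1.1, 1.5),
        "dialysis_time_coefficient": (0.08, 0.16),
        "withdrawal_prob": (0.005, 0.02),
        "conservative_care_fraction": (0.0, 0.05),
        "median_wait": (3.5, 5.5),
        "graft_failure_first_year": (0.05, 0.10),
        "graft_failure_later": (0.03, 0.05),
        "perioperative_complication_prob": (0.2, 0.4),
        "hr_point": (1.05, 1.9),
        "hr_ci_halfwidth": (0.08, 0.25),  # multiplicative CI half-width
        "dialysis_initial": (90_000, 130_000),
        "dialysis_maintenance": (60_000, 90_000),
        "transplant_initial_uncomplicated": (50_000, 70_000),
        "transplant_initial_complicated": (80_000, 110_000),
        "transplant_maintenance": (10_000, 16_000),
        "comorbidity_annual_addon": (1_000, 10_000),
        "cost_se_fraction": (0.03, 0.08),
    }


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded recipe for one synthetic parameter set."""

    seed: int = 0
    profile: ComorbidityProfile = ComorbidityProfile(45, Comorbidity.NONE)
    ranges: dict = field(default_factory=_default_ranges)

    def validate(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise DomainError(f"range for '{name}' is degenerate: low {lo} > high {hi}")


def generate_parameter_set(spec: FixtureSpec) -> ParameterSet:
    """Generate a validated ParameterSet as a pure function of (seed, spec).

    Baseline dialysis mortality is Gompertz across 5-year age bands, so it
    increases with age by construction; post-transplant mortality is a
    constant multiple of the zero-exposure dialysis baseline; hazard-ratio
    confidence intervals are multiplicatively symmetric (lognormal-shaped)
    around the point.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    R = {**_default_ranges(), **spec.ranges}

    def u(name):
        lo, hi = R[name]
        return float(rng.uniform(lo, hi))

    intercept, slope = u("gompertz_intercept"), u("gompertz_slope")
    bands = list(range(AGE_BAND_START, 101, AGE_BAND_WIDTH))
    base = {b: round(intercept * math.exp(slope * (b - AGE_BAND_START)), 6) for b in bands}
    ratio = u("post_transplant_ratio")
    post = {b: round(r * ratio, 6) for b, r in base.items()}

    def hr_draw():
        pt = u("hr_point")
        h = u("hr_ci_halfwidth")
        return HazardRatio(round(pt, 4), round(pt / (1 + h), 4), round(pt * (1 + h), 4))

    hr_dial = {Comorbidity.NONE: UNIT_HR}
    hr_graft = {Comorbidity.NONE: UNIT_HR}
    for com in _COMORBIDITIES:
        hr_dial[com] = hr_draw()
        hr_graft[com] = hr_draw()

    gf_first, gf_later = u("graft_failure_first_year"), u("graft_failure_later")
    trans = TransitionInputs(
        baseline_dialysis_death_rate_by_age=base,
        post_transplant_death_rate_by_age=post,
        dialysis_time_coefficient=round(u("dialysis_time_coefficient"), 4),
        withdrawal_prob=round(u("withdrawal_prob"), 4),
        conservative_care_fraction=round(u("conservative_care_fraction"), 4),
        median_wait=round(u("median_wait"), 2),
        graft_failure_prob_by_graft_age={0: round(gf_first, 4), 1: round(gf_later, 4),
                                         5: round(min(gf_later * 1.2, 1.0), 4)},
        perioperative_complication_prob=round(u("perioperative_complication_prob"), 4),
    )

    se_frac = u("cost_se_fraction")

    def cost(name):
        m = round(u(name), 2)
        return CostItem(m, round(m * se_frac, 2))

    addons = {Comorbidity.NONE: CostItem(0.0, 0.0)}
    for com in _COMORBIDITIES:
        addons[com] = cost("comorbidity_annual_addon")
    costs = CostSet(
        dialysis_initial=cost("dialysis_initial"),
        dialysis_maintenance=cost("dialysis_maintenance"),
        transplant_initial_uncomplicated=cost("transplant_initial_uncomplicated"),
        transplant_initial_complicated=cost("transplant_initial_complicated"),
        transplant_maintenance=cost("transplant_maintenance"),
        comorbidity_annual_addon=addons,
        currency="synthetic",
    )

    ps = ParameterSet(
        profile=spec.profile, hr=HazardRatioSet(hr_dial, hr_graft), trans=trans,
        costs=costs, config=ModelConfig(rng_seed=spec.seed),
        provenance=f"synthetic(seed={spec.seed})",
    )
    return ps.validate()


def default_fixture() -> ParameterSet:
    """The packaged, hand-calibrated parameter set (see module docstring)."""
    text = resources.files("renalcea").joinpath("data/default.yaml").read_text()
    return from_dict(yaml.safe_load(text), provenance="renalcea:data/default.yaml")
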