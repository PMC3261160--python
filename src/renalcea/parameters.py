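"""Typed model inputs: clinical transition inputs, hazard ratios, costs, run config.

The model consumes a single :class:`ParameterSet` bundling a patient profile
(age at listing plus a single co-morbidity tag), adjusted mortality hazard
ratios for dialysis and for life with a functioning graft, the transition
inputs (age-banded baseline death rates, the exponential time-on-dialysis
coefficient, waiting-time and graft-failure probabilities), annual state
costs with standard errors, and the run configuration (discount rate,
half-cycle correction, horizon).

Parameter files are YAML or JSON (auto-detected by extension) under a
versioned schema; see ``data/default.yaml`` for an annotated example.
All currency fields are unit-agnostic decimals labelled by a currency tag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import yaml

from .errors import DomainError, FormatError, ValidationError

SCHEMA_VERSION = 1

#: Age bands for baseline rates: 5-year bands starting at this age.
AGE_BAND_START = 20
AGE_BAND_WIDTH = 5


class Comorbidity(str, Enum):
    """Single co-morbidity tag; profiles carry exactly one (never combined)."""

    NONE = "none"
    CARDIOVASCULAR = "cardiovascular"
    DIABETES = "diabetes"
    STROKE = "stroke"
    OBESITY = "obesity"
    SMOKER = "smoker"


def annual_transplant_prob(median_wait: float) -> float:
    """Constant annual transplant probability from a median waiting time.

    Waiting time is geometric with constant annual probability ``p`` chosen so
    the median time-to-transplant equals ``median_wait`` years:
    ``p = 1 - 2**(-1/median_wait)``. An infinite wait means never transplanted.

    Parameters
    ----------
    median_wait : float
        Median years to deceased-donor transplant; must be > 0 (``inf`` allowed).

    Returns
    -------
    float
        Annual transplant probability in (0, 1); 0 for an infinite wait.
    """
    if math.isinf(median_wait):
        return 0.0
    if median_wait <= 0:
        raise DomainError(f"median_wait must be > 0 or inf, got {median_wait}")
    return 1.0 - 2.0 ** (-1.0 / median_wait)


@dataclass(frozen=True)
class ComorbidityProfile:
    """Age at listing and the (single) co-morbidity of the modelled cohort."""

    age_at_listing: int
    comorbidity: Comorbidity = Comorbidity.NONE

    def validate(self) -> None:
        if not isinstance(self.age_at_listing, int) or isinstance(self.age_at_listing, bool):
            raise ValidationError("profile.age_at_listing", "must be an integer")
        if not 18 <= self.age_at_listing <= 80:
            raise ValidationError("profile.age_at_listing", "must be within 18-80")
        if not isinstance(self.comorbidity, Comorbidity):
            raise ValidationError("profile.comorbidity", "unknown co-morbidity tag")


@dataclass(frozen=True)
class HazardRatio:
    """Adjusted hazard ratio with its 95% confidence interval."""

    point: float
    ci_low: float
    ci_high: float

    @property
    def ln_sd(self) -> float:
        """Log-scale SD implied by the 95% CI: (ln hi - ln lo) / (2 * 1.96)."""
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * 1.96)

    def validate(self, name: str) -> None:
        for part, v in (("point", self.point), ("ci_low", self.ci_low), ("ci_high", self.ci_high)):
            if not (isinstance(v, (int, float)) and v > 0 and math.isfinite(v)):
                raise ValidationError(f"{name}.{part}", "hazard ratio must be a positive finite number")
        if not self.ci_low <= self.point <= self.ci_high:
            raise ValidationError(name, "must satisfy ci_low <= point <= ci_high")


#: Degenerate unit hazard ratio used for the no-comorbidity reference.
UNIT_HR = HazardRatio(1.0, 1.0, 1.0)


@dataclass(frozen=True)
class HazardRatioSet:
    """Per-comorbidity adjusted HRs for death on dialysis and with a graft."""

    dialysis: Mapping[Comorbidity, HazardRatio]
    graft: Mapping[Comorbidity, HazardRatio]

    def validate(self, required: Comorbidity | None = None) -> None:
        for arm, table in (("dialysis", self.dialysis), ("graft", self.graft)):
            for com, hr in table.items():
                hr.validate(f"hr.{arm}.{com.value}")
            none_hr = table.get(Comorbidity.NONE, UNIT_HR)
            if not (none_hr.point == none_hr.ci_low == none_hr.ci_high == 1.0):
                raise ValidationError(f"hr.{arm}.none", "reference HR must be exactly 1 with degenerate CI")
            if required is not None and required not in table:
                raise ValidationError(f"hr.{arm}.{required.value}",
                                      "hazard ratio required for the profile co-morbidity")


@dataclass(frozen=True)
class TransitionInputs:
    """Clinical transition inputs of the state-transition model.

    ``baseline_dialysis_death_rate_by_age`` and
    ``post_transplant_death_rate_by_age`` are annual event rates keyed by
    5-year age-band start (20, 25, ...); ages beyond the last band use the
    last band. ``dialysis_time_coefficient`` is the per-year exponent of the
    exponential effect of cumulative time on dialysis on the dialysis death
    rate. ``graft_failure_prob_by_graft_age`` is keyed by completed graft
    years (clamped to its last key). ``median_wait`` of 0 means transplant is
    certain in the first cycle; ``annual_transplant_prob`` may override the
    geometric derivation from the median wait.
    """

    baseline_dialysis_death_rate_by_age: Mapping[int, float]
    post_transplant_death_rate_by_age: Mapping[int, float]
    dialysis_time_coefficient: float
    withdrawal_prob: float
    conservative_care_fraction: float
    median_wait: float
    graft_failure_prob_by_graft_age: Mapping[int, float]
    perioperative_complication_prob: float
    annual_transplant_prob: float | None = None

    def transplant_prob(self) -> float:
        """Effective annual transplant probability for the listed cohort."""
        if self.annual_transplant_prob is not None:
            return self.annual_transplant_prob
        if self.median_wait == 0:
            return 1.0
        return annual_transplant_prob(self.median_wait)

    def validate(self) -> None:
        for name, table in (
            ("trans.baseline_dialysis_death_rate_by_age", self.baseline_dialysis_death_rate_by_age),
            ("trans.post_transplant_death_rate_by_age", self.post_transplant_death_rate_by_age),
        ):
            if not table:
                raise ValidationError(name, "must not be empty")
            for band, rate in table.items():
                if (band - AGE_BAND_START) % AGE_BAND_WIDTH != 0 or band < AGE_BAND_START:
                    raise ValidationError(name, f"age bands must be 5-year bands from {AGE_BAND_START}; got {band}")
                if not (rate >= 0 and math.isfinite(rate)):
                    raise ValidationError(f"{name}[{band}]", "rate must be >= 0")
        if not self.graft_failure_prob_by_graft_age:
            raise ValidationError("trans.graft_failure_prob_by_graft_age", "must not be empty")
        for k, p in self.graft_failure_prob_by_graft_age.items():
            if k < 0 or not 0 <= p <= 1:
                raise ValidationError(f"trans.graft_failure_prob_by_graft_age[{k}]",
                                      "graft age >= 0 and probability in [0,1]")
        if not self.dialysis_time_coefficient >= 0:
            raise ValidationError("trans.dialysis_time_coefficient", "must be >= 0")
        for name, p in (
            ("trans.withdrawal_prob", self.withdrawal_prob),
            ("trans.conservative_care_fraction", self.conservative_care_fraction),
            ("trans.perioperative_complication_prob", self.perioperative_complication_prob),
        ):
            if not 0 <= p <= 1:
                raise ValidationError(name, "probability must be in [0,1]")
        if not (self.median_wait >= 0 or math.isinf(self.median_wait)):
            raise ValidationError("trans.median_wait", "must be >= 0 (0 = immediate transplant) or inf")
        if self.annual_transplant_prob is not None and not 0 <= self.annual_transplant_prob <= 1:
            raise ValidationError("trans.annual_transplant_prob", "probability must be in [0,1]")


@dataclass(frozen=True)
class CostItem:
    """A cost with its standard error (both in the file's currency units)."""

    mean: float
    se: float = 0.0

    def validate(self, name: str) -> None:
        if not (self.mean >= 0 and math.isfinite(self.mean)):
            raise ValidationError(name, f"{name} >= 0")
        if not (self.se >= 0 and math.isfinite(self.se)):
            raise ValidationError(f"{name}.se", "standard error must be >= 0")


@dataclass(frozen=True)
class CostSet:
    """Annual and one-off state costs (currency-tag agnostic)."""

    dialysis_initial: CostItem
    dialysis_maintenance: CostItem
    transplant_initial_uncomplicated: CostItem
    transplant_initial_complicated: CostItem
    transplant_maintenance: CostItem
    comorbidity_annual_addon: Mapping[Comorbidity, CostItem]
    currency: str = "AUD2008"

    def validate(self, required: Comorbidity | None = None) -> None:
        for name in ("dialysis_initial", "dialysis_maintenance",
                     "transplant_initial_uncomplicated", "transplant_initial_complicated",
                     "transplant_maintenance"):
            getattr(self, name).validate(f"costs.{name}")
        for com, item in self.comorbidity_annual_addon.items():
            item.validate(f"costs.comorbidity_annual_addon.{com.value}")
        if required is not None and required not in self.comorbidity_annual_addon:
            raise ValidationError(f"costs.comorbidity_annual_addon.{required.value}",
                                  "annual add-on required for the profile co-morbidity")


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration: discounting, correction, horizon, simulation sizes."""

    discount_rate: float = 0.05
    cycle_length: float = 1.0
    half_cycle_correction: bool = True
    cohort_size: int = 10_000
    psa_iterations: int = 10_000
    rng_seed: int = 0
    max_age: int | None = 100

    def validate(self) -> None:
        if not 0 <= self.discount_rate < 1:
            raise ValidationError("config.discount_rate", "must be in [0,1)")
        if self.cycle_length != 1.0:
            raise ValidationError("config.cycle_length", "annual cycles only (cycle_length = 1)")
        if self.cohort_size < 1:
            raise ValidationError("config.cohort_size", "must be >= 1")
        if self.psa_iterations < 1:
            raise ValidationError("config.psa_iterations", "must be >= 1")
        if self.max_age is not None and not 18 < self.max_age <= 120:
            raise ValidationError("config.max_age", "must be in (18,120] or null")


@dataclass(frozen=True)
class ParameterSet:
    """The full input bundle for one model run."""

    profile: ComorbidityProfile
    hr: HazardRatioSet
    trans: TransitionInputs
    costs: CostSet
    config: ModelConfig
    provenance: str = "in-memory"

    def validate(self) -> "ParameterSet":
        self.profile.validate()
        self.hr.validate(required=self.profile.comorbidity)
        self.trans.validate()
        self.costs.validate(required=self.profile.comorbidity)
        self.config.validate()
        if self.config.max_age is not None and self.config.max_age <= self.profile.age_at_listing:
            raise ValidationError("config.max_age", "must exceed profile.age_at_listing")
        return self

    # -- convenience accessors used across the pipeline ------------------
    def hr_dialysis(self) -> HazardRatio:
        return self.hr.dialysis[self.profile.comorbidity]

    def hr_graft(self) -> HazardRatio:
        return self.hr.graft[self.profile.comorbidity]

    def addon(self) -> CostItem:
        return self.costs.comorbidity_annual_addon[self.profile.comorbidity]

    def with_profile(self, age: int | None = None,
                     comorbidity: Comorbidity | None = None) -> "ParameterSet":
        prof = ComorbidityProfile(
            age if age is not None else self.profile.age_at_listing,
            comorbidity if comorbidity is not None else self.profile.comorbidity,
        )
        return replace(self, profile=prof)

    def with_wait(self, median_wait: float) -> "ParameterSet":
        return replace(self, trans=replace(self.trans, median_wait=median_wait,
                                           annual_transplant_prob=None))


def band_for_age(age: float, table: Mapping[int, float]) -> float:
    """Look up an age-banded rate, clamping to the first/last band."""
    if age < 18:
        raise DomainError(f"age {age} below model support (18)")
    top = max(table)
    band = AGE_BAND_START + AGE_BAND_WIDTH * int((age - AGE_BAND_START) // AGE_BAND_WIDTH)
    band = min(max(band, AGE_BAND_START), top)
    return table[band]


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def _hr_to_dict(hr: HazardRatio) -> dict:
    return {"hr": hr.point, "ci95": [hr.ci_low, hr.ci_high]}


def _cost_to_dict(c: CostItem) -> dict:
    return {"mean": c.mean, "se": c.se}


def to_dict(ps: ParameterSet) -> dict:
    """Plain-data representation under the versioned file schema."""
    return {
        "schema_version": SCHEMA_VERSION,
        "profile": {
            "age_at_listing": ps.profile.age_at_listing,
            "comorbidity": ps.profile.comorbidity.value,
        },
        "hazard_ratios": {
            arm: {com.value: _hr_to_dict(hr) for com, hr in table.items()}
            for arm, table in (("dialysis", ps.hr.dialysis), ("graft", ps.hr.graft))
        },
        "transitions": {
            "baseline_dialysis_death_rate_by_age":
                {int(k): v for k, v in ps.trans.baseline_dialysis_death_rate_by_age.items()},
            "post_transplant_death_rate_by_age":
                {int(k): v for k, v in ps.trans.post_transplant_death_rate_by_age.items()},
            "dialysis_time_coefficient": ps.trans.dialysis_time_coefficient,
            "withdrawal_prob": ps.trans.withdrawal_prob,
            "conservative_care_fraction": ps.trans.conservative_care_fraction,
            "median_wait": ps.trans.median_wait,
            "annual_transplant_prob": ps.trans.annual_transplant_prob,
            "graft_failure_prob_by_graft_age":
                {int(k): v for k, v in ps.trans.graft_failure_prob_by_graft_age.items()},
            "perioperative_complication_prob": ps.trans.perioperative_complication_prob,
        },
        "costs": {
            "currency": ps.costs.currency,
            "dialysis_initial": _cost_to_dict(ps.costs.dialysis_initial),
            "dialysis_maintenance": _cost_to_dict(ps.costs.dialysis_maintenance),
            "transplant_initial_uncomplicated": _cost_to_dict(ps.costs.transplant_initial_uncomplicated),
            "transplant_initial_complicated": _cost_to_dict(ps.costs.transplant_initial_complicated),
            "transplant_maintenance": _cost_to_dict(ps.costs.transplant_maintenance),
            "comorbidity_annual_addon":
                {com.value: _cost_to_dict(c) for com, c in ps.costs.comorbidity_annual_addon.items()},
        },
        "config": {
            "discount_rate": ps.config.discount_rate,
            "cycle_length": ps.config.cycle_length,
            "half_cycle_correction": ps.config.half_cycle_correction,
            "cohort_size": ps.config.cohort_size,
            "psa_iterations": ps.config.psa_iterations,
            "rng_seed": ps.config.rng_seed,
            "max_age": ps.config.max_age,
        },
    }


def _require(d: Mapping, key: str, where: str):
    if key not in d:
        raise FormatError(f"missing key '{key}' in {where}")
    return d[key]


def _parse_hr_table(d: Mapping, where: str) -> dict[Comorbidity, HazardRatio]:
    out = {}
    for name, entry in d.items():
        try:
            com = Comorbidity(name)
        except ValueError:
            raise FormatError(f"unknown co-morbidity '{name}' in {where}")
        ci = entry.get("ci95", [entry["hr"], entry["hr"]])
        out[com] = HazardRatio(float(entry["hr"]), float(ci[0]), float(ci[1]))
    return out


def _parse_cost(d: Mapping, where: str) -> CostItem:
    if isinstance(d, (int, float)):
        return CostItem(float(d), 0.0)
    return CostItem(float(_require(d, "mean", where)), float(d.get("se", 0.0)))


def from_dict(data: Mapping, provenance: str = "dict") -> ParameterSet:
    """Build and validate a :class:`ParameterSet` from plain data."""
    if not isinstance(data, Mapping):
        raise FormatError("parameter document must be a mapping")
    version = data.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise FormatError(f"unsupported schema_version {version} (expected {SCHEMA_VERSION})")

    prof_d = _require(data, "profile", "document")
    try:
        com = Comorbidity(prof_d.get("comorbidity", "none"))
    except ValueError:
        raise FormatError(f"unknown co-morbidity '{prof_d.get('comorbidity')}' in profile")
    profile = ComorbidityProfile(int(_require(prof_d, "age_at_listing", "profile")), com)

    hr_d = _require(data, "hazard_ratios", "document")
    hr = HazardRatioSet(
        dialysis=_parse_hr_table(_require(hr_d, "dialysis", "hazard_ratios"), "hazard_ratios.dialysis"),
        graft=_parse_hr_table(_require(hr_d, "graft", "hazard_ratios"), "hazard_ratios.graft"),
    )

    tr = _require(data, "transitions", "document")
    mw = tr.get("median_wait", 4.5)
    trans = TransitionInputs(
        baseline_dialysis_death_rate_by_age={int(k): float(v) for k, v in
                                             _require(tr, "baseline_dialysis_death_rate_by_age", "transitions").items()},
        post_transplant_death_rate_by_age={int(k): float(v) for k, v in
                                           _require(tr, "post_transplant_death_rate_by_age", "transitions").items()},
        dialysis_time_coefficient=float(tr.get("dialysis_time_coefficient", 0.0)),
        withdrawal_prob=float(tr.get("withdrawal_prob", 0.0)),
        conservative_care_fraction=float(tr.get("conservative_care_fraction", 0.0)),
        median_wait=float("inf") if mw in ("inf", ".inf") else float(mw),
        annual_transplant_prob=(None if tr.get("annual_transplant_prob") is None
                                else float(tr["annual_transplant_prob"])),
        graft_failure_prob_by_graft_age={int(k): float(v) for k, v in
                                         _require(tr, "graft_failure_prob_by_graft_age", "transitions").items()},
        perioperative_complication_prob=float(tr.get("perioperative_complication_prob", 0.0)),
    )

    co = _require(data, "costs", "document")
    costs = CostSet(
        dialysis_initial=_parse_cost(_require(co, "dialysis_initial", "costs"), "costs.dialysis_initial"),
        dialysis_maintenance=_parse_cost(_require(co, "dialysis_maintenance", "costs"), "costs.dialysis_maintenance"),
        transplant_initial_uncomplicated=_parse_cost(
            _require(co, "transplant_initial_uncomplicated", "costs"), "costs.transplant_initial_uncomplicated"),
        transplant_initial_complicated=_parse_cost(
            _require(co, "transplant_initial_complicated", "costs"), "costs.transplant_initial_complicated"),
        transplant_maintenance=_parse_cost(_require(co, "transplant_maintenance", "costs"),
                                           "costs.transplant_maintenance"),
        comorbidity_annual_addon={
            Comorbidity(name): _parse_cost(entry, f"costs.comorbidity_annual_addon.{name}")
            for name, entry in co.get("comorbidity_annual_addon", {}).items()},
        currency=str(co.get("currency", "AUD2008")),
    )

    cf = data.get("config", {})
    config = ModelConfig(
        discount_rate=float(cf.get("discount_rate", 0.05)),
        cycle_length=float(cf.get("cycle_length", 1.0)),
        half_cycle_correction=bool(cf.get("half_cycle_correction", True)),
        cohort_size=int(cf.get("cohort_size", 10_000)),
        psa_iterations=int(cf.get("psa_iterations", 10_000)),
        rng_seed=int(cf.get("rng_seed", 0)),
        max_age=(None if cf.get("max_age", 100) is None else int(cf.get("max_age", 100))),
    )

    return ParameterSet(profile, hr, trans, costs, config, provenance=provenance).validate()


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and validate a parameter file (YAML or JSON by extension)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"parameter file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as e:
            raise FormatError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    else:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as e:
            mark = getattr(e, "problem_mark", None)
            line = f" at line {mark.line + 1}" if mark is not None else ""
            raise FormatError(f"{path}: invalid YAML{line}") from e
    return from_dict(data, provenance=str(path))


def save_parameters(ps: ParameterSet, path: str | Path) -> Path:
    """Write a ParameterSet to YAML or JSON (by extension); round-trips exactly."""
    path = Path(path)
    data = to_dict(ps)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False, default_flow_style=False))
    return path
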