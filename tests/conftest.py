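import math

import pytest

from renalcea import (Comorbidity, ComorbidityProfile, CostItem, CostSet,
                      HazardRatioSet, ModelConfig, ParameterSet,
                      TransitionInputs, default_fixture)
from renalcea.parameters import UNIT_HR


@pytest.fixture(scope="session")
def default_params() -> ParameterSet:
    return default_fixture()


def flat_params(q_dial: float = 0.1, q_graft: float = 0.05, p_tx: float = 0.0,
                graft_failure: float = 0.0, age: int = 45, max_age: int | None = 100,
                discount: float = 0.05, half_cycle: bool = True,
                withdrawal: float = 0.0, conservative: float = 0.0,
                gamma: float = 0.0, dial_cost: float = 0.0, tx_cost: float = 0.0,
                ) -> ParameterSet:
    """Constant-probability toy model: flat hazards, explicit transplant prob.

    With gamma = 0 and flat age bands the process is time-homogeneous, which
    makes closed forms and exhaustive path enumeration tractable.
    """

    def rate(q):
        return 1e9 if q >= 1 else -math.log1p(-q)

    bands = {b: rate(q_dial) for b in range(20, 121, 5)}
    post = {b: rate(q_graft) for b in range(20, 121, 5)}
    trans = TransitionInputs(
        baseline_dialysis_death_rate_by_age=bands,
        post_transplant_death_rate_by_age=post,
        dialysis_time_coefficient=gamma,
        withdrawal_prob=withdrawal,
        conservative_care_fraction=conservative,
        median_wait=math.inf,
        annual_transplant_prob=p_tx,
        graft_failure_prob_by_graft_age={0: graft_failure},
        perioperative_complication_prob=0.0,
    )
    zero = CostItem(0.0, 0.0)
    costs = CostSet(
        dialysis_initial=CostItem(dial_cost, 0.0),
        dialysis_maintenance=CostItem(dial_cost, 0.0),
        transplant_initial_uncomplicated=CostItem(tx_cost, 0.0),
        transplant_initial_complicated=CostItem(tx_cost, 0.0),
        transplant_maintenance=CostItem(tx_cost, 0.0),
        comorbidity_annual_addon={Comorbidity.NONE: zero},
    )
    hr = HazardRatioSet({Comorbidity.NONE: UNIT_HR}, {Comorbidity.NONE: UNIT_HR})
    cfg = ModelConfig(discount_rate=discount, half_cycle_correction=half_cycle,
                      max_age=max_age, rng_seed=7)
    return ParameterSet(ComorbidityProfile(age, Comorbidity.NONE), hr, trans,
                        costs, cfg, provenance="toy").validate()
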