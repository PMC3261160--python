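"""Age-by-waiting-time scenario grids, including the zero-wait scenario.

Each cell rebuilds the parameter set with that age at listing and median
wait (a wait of 0 means a deceased-donor organ is certain in the first
cycle — the unlimited-supply scenario) and evaluates the incremental
outcomes of listing against remaining on dialysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DomainError
from .parameters import ParameterSet
from .sensitivity import _increment


@dataclass
class ScenarioGrid:
    """Complete age x wait grid of incremental outcomes (long format)."""

    ages: list[int]
    waits: list[float]
    frame: pd.DataFrame  # age, wait, delta_effect, delta_cost, icer, dominance

    def cell(self, age: int, wait: float) -> pd.Series:
        m = (self.frame.age == age) & (self.frame.wait == wait)
        return self.frame[m].iloc[0]


def evaluate_grid(base: ParameterSet, ages, waits) -> ScenarioGrid:
    """Evaluate the incremental outcome surface over ages and median waits."""
    ages = [int(a) for a in ages]
    waits = [float(w) for w in waits]
    if not ages or not waits:
        raise DomainError("ages and waits must be non-empty")
    if sorted(set(ages)) != ages or sorted(set(waits)) != waits:
        raise DomainError("axes must be strictly increasing")
    rows = []
    for a in ages:
        for w in waits:
            if w < 0:
                raise DomainError("waits must be >= 0")
            incr = _increment(base.with_profile(age=a).with_wait(w))
            rows.append((a, w, incr.delta_effect, incr.delta_cost,
                         incr.icer, incr.dominance.value))
    frame = pd.DataFrame(rows, columns=["age", "wait", "delta_effect", "delta_cost",
                                        "icer", "dominance"])
    return ScenarioGrid(ages, waits, frame)
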