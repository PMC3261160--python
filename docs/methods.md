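# Methods

## Model structure

The model is a discrete-time (annual-cycle) closed-cohort state-transition
model with five compartments: dialysis while waitlisted (or unlisted,
depending on strategy), functioning graft, dialysis after graft failure,
conservative care, and death. A cohort enters 100% on dialysis at the
profile's age at listing; the conservative-care fraction occupies its own
compartment for one cycle (it contributes half a life-year and no renal
replacement cost) and is dead from cycle 1. The model terminates when the
dead mass reaches 1 − 10⁻¹⁰ or the cohort reaches `max_age` (default 100),
which acts as a strict horizon: death is forced in the cycle that would end
at `max_age`, so a zero-mortality cohort accrues exactly `max_age − age`
undiscounted life-years.

Two time scales matter besides age: cumulative years on dialysis (drives
the exponential exposure effect, pauses while a graft functions, resumes
after graft failure) and graft age (drives graft failure). Both are integer
clocks, and the engine expands states by clock value ("tunnel" states), so
the time-inhomogeneous process is exactly Markov in the expanded space — no
approximation. Internally the expansion is cheap because each clock is
determined by bookkeeping indices: waitlisted exposure equals the cycle
index, graft states are indexed by transplant cycle, and post-graft states
by cumulative exposure.

### Competing events within a cycle

Events are evaluated at the end of each annual cycle in a fixed, documented
order: death first; transplant among surviving listed dialysis patients;
graft failure among surviving recipients. Dialysis withdrawal is treated as
death in the concurrent year and is therefore added at the probability
scale to the converted dialysis death probability (clipped at 1). Rates are
converted to annual probabilities by `p = 1 − exp(−rate)`.

### State membership and rewards

Occupancy is measured at cycle start; a cohort member alive at the start of
cycle `t` accrues one life-year and that cycle's costs, weighted by the
discount factor `(1+r)^−(t+0.5)` (half-cycle correction: rewards are
valued mid-cycle) or `(1+r)^−t` with the correction off. Costs per cycle:
initial dialysis cost in the first year of each dialysis episode (entry and
re-entry after graft failure), maintenance thereafter; the transplant-year
cost is the complication-probability-weighted mix of the complicated and
uncomplicated initial costs, maintenance thereafter; co-morbidity add-ons
accrue in every live renal-replacement year. Perioperative complications
affect costs only, not mortality (mortality differences enter only through
the baseline rates and hazard ratios); a graft-survival effect of delayed
graft function could be added through the graft-failure table if ever
needed.

## Parameters

| Parameter | Units | Default | Why |
|---|---|---|---|
| `discount_rate` | /year | 0.05 | conventional health-economics rate |
| `half_cycle_correction` | flag | on | mid-cycle valuation of rewards |
| `median_wait` | years | 4.5 | mid-point of the 4–5-year deceased-donor median wait; 0 = certain transplant in the first cycle (unlimited-organ scenario) |
| `dialysis_time_coefficient` γ | /year | 0.15 | exponential exposure effect on dialysis mortality (see calibration) |
| `withdrawal_prob` | /year | 0.003 | small annual dialysis withdrawal, fatal in-year |
| `conservative_care_fraction` | — | 0.02 | small share never starting renal replacement therapy |
| `graft_failure_prob_by_graft_age` | /year | 0.07 / 0.03 / 0.025 | higher first-year (technical/rejection) failure, low attrition later |
| `perioperative_complication_prob` | — | 0.30 | share of transplant years billed at the complicated rate |
| `max_age` | years | 100 | absorbing horizon |
| `cohort_size` | — | 10,000 | microsimulation size |
| `psa_iterations` | — | 10,000 | probabilistic sensitivity analysis size |

The annual transplant probability is derived from the median wait as
`1 − 2^(−1/m)` — the constant-hazard (geometric) waiting-time distribution
is the simplest one consistent with a stated median. An explicit
`annual_transplant_prob` in the parameter file overrides it.

Age-banded rates use 5-year bands from age 20; ages past the last band
reuse it, matching registry reporting conventions.

## The synthetic default fixture

Appendix-grade registry inputs (age-specific mortality on dialysis and
post-transplant, Cox-adjusted co-morbidity hazard ratios, national cost
schedules) are not redistributable, so the packaged default parameter set
is synthetic and *calibrated to qualitative behaviour only*:

- baseline dialysis mortality is Gompertz, `0.008·e^{0.075(age−20)}`;
- post-transplant mortality is the baseline times a multiplier that starts
  at 1.9 at age 20 and declines by 0.018/year to a floor of 1. The
  multiplier exceeds 1 at young ages — a fresh transplant is initially
  riskier than incident dialysis — while the *comparator's* risk compounds
  at `e^{0.15·exposure}`, so the transplant advantage emerges with time.
  This single mechanism produces the delayed crossover of cumulative
  incremental benefit (negative at year 2, positive by year 8, crossing
  between years 4 and 6) without a graft-age-specific mortality table;
- costs (2008 AUD scale): dialysis 76,000 initial / 45,000 maintenance per
  year, transplant 115,000 uncomplicated / 155,000 complicated initial and
  13,500 maintenance per year, with ~5% standard errors and co-morbidity
  add-ons of 2,500–9,000 per year.

Under this fixture: listing dominates (saves money and life-years) for a
25-year-old; incremental life-years fall monotonically with age at
listing; zero waiting time improves the gain at every age; and the PSA
cloud for a 45-year-old diabetic sits in the northeast quadrant. These are
the orderings the tests assert. The fixture does **not** reproduce any
published absolute life-year, cost, or ICER value, and several real-data
features are deliberately absent: donor-quality stratification, living
donors and re-transplantation, co-existing multiple co-morbidities,
age-dependent waiting times, and non-proportional co-morbidity effects.
Passing tests therefore validate the *engine and its orderings*, not
real-world magnitudes.

The seeded generator (`generate_parameter_set`) draws fixture families
with the same structure: Gompertz baselines (monotone in age by
construction), multiplicatively symmetric hazard-ratio CIs (lognormal
shape), positive costs with proportional standard errors. Generation is a
pure function of `(seed, spec)`.

## Sensitivity analyses

Hazard ratios are sampled lognormally with the median anchored at the
point estimate and log-SD `(ln hi − ln lo)/(2·1.96)`; anchoring the median
(not the mean) preserves the reported ratio under exponentiation.
Degenerate CIs collapse to the point. Costs are sampled from gamma
distributions moment-matched to (mean, SE); zero SE collapses to the mean
(including genuinely zero-cost items such as the no-comorbidity add-on).
Which quantities are uncertain is declared by the parameter file: hazard
ratios and costs by default; transition probabilities are explored through
one-way sweeps instead. Each PSA iteration uses an independent RNG stream
spawned from one seed sequence, so results do not depend on the order in
which parameters are sampled.

One-way sweeps re-evaluate both strategies over a grid of a single scalar
(waiting time, discount rate, γ, hazard ratios, any unit cost) with all
else at base case; the scenario module does the same over an age ×
median-wait grid, with wait 0 meaning transplant probability 1 in the
first cycle rather than an instantaneous state swap, keeping cycle
accounting uniform.

## Numerical choices

- Conservation is maintained identically by construction; tests assert
  cycle sums equal 1 within 10⁻¹⁰ and transition rows sum to 1 within
  10⁻¹².
- The ICER is rounded half-up to the nearest whole currency unit and
  reported only for northeast trade-offs; a gain at zero or negative
  incremental cost is classified dominant, zero incremental effect leaves
  dominance undefined (no ICER, warning on threshold classification).
- The cohort engine is validated against two independent oracles: the
  closed-form discounted geometric series for a constant-hazard,
  no-transplant cohort (agreement < 10⁻⁸) and exhaustive path enumeration
  for a three-state, five-cycle toy (agreement < 10⁻¹²). Under the
  start-of-cycle counting convention the undiscounted constant-hazard life
  expectancy is `1/q` over an open horizon.
- The microsimulation uses the same probability functions and event order
  as the expectation engine; at n = 10,000 its per-cycle compartment
  occupancies agree with the cohort trace within three binomial standard
  errors for ≥ 95% of (cycle, compartment) cells.
- Problem sizes in the shipped checks (2,000 PSA iterations, one
  10,000-person microsimulation) were chosen to keep the full
  verification run at a few seconds while leaving Monte-Carlo noise an
  order of magnitude below the asserted margins.

## Known limitations

- Single co-morbidity tags only; effects of co-existing conditions are not
  modelled.
- The waiting-time distribution is geometric; real allocation queues have
  duration dependence.
- Post-transplant mortality varies with age but not graft age; the early
  surgical excess is carried by the age multiplier described above.
- No quality-of-life weighting (life-years, not QALYs), no currency
  conversion, no donor-quality or living-donor pathways, and no
  re-transplantation.
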