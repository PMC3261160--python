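# Packaged default parameter set (schema version 1).
#
# This is a hand-calibrated SYNTHETIC fixture emulating the structure of
# registry-derived clinical inputs and national cost schedules for an
# end-stage kidney disease listing-vs-dialysis decision model. It is tuned
# to qualitative behaviour only (orderings by age and waiting time, the
# delayed crossover of cumulative incremental benefit, quadrant placement
# of probabilistic results), not to any published absolute value.
#
# Units: rates are annual events/year; probabilities are per annual cycle;
# costs are per year (or one-off where named "initial") in the tagged
# currency. Age-banded tables use 5-year bands keyed by band start; ages
# past the last band reuse it.
schema_version: 1

profile:
  age_at_listing: 45
  comorbidity: none

hazard_ratios:
  # Adjusted all-cause mortality hazard ratios (95% CI), by co-morbidity,
  # for listed patients on dialysis and for recipients with a functioning
  # graft. The no-comorbidity reference is exactly 1 with a degenerate CI.
  dialysis:
    none:           {hr: 1.0,  ci95: [1.0, 1.0]}
    cardiovascular: {hr: 1.5,  ci95: [1.30, 1.73]}
    diabetes:       {hr: 1.55, ci95: [1.35, 1.78]}
    stroke:         {hr: 1.45, ci95: [1.26, 1.67]}
    obesity:        {hr: 1.15, ci95: [1.00, 1.32]}
    smoker:         {hr: 1.30, ci95: [1.13, 1.50]}
  graft:
    none:           {hr: 1.0,  ci95: [1.0, 1.0]}
    cardiovascular: {hr: 1.45, ci95: [1.26, 1.67]}
    diabetes:       {hr: 1.50, ci95: [1.30, 1.73]}
    stroke:         {hr: 1.40, ci95: [1.22, 1.61]}
    obesity:        {hr: 1.20, ci95: [1.04, 1.38]}
    smoker:         {hr: 1.35, ci95: [1.17, 1.55]}

transitions:
  # Gompertz-shaped baseline at zero dialysis exposure:
  # 0.008 * exp(0.075 * (band - 20)).
  baseline_dialysis_death_rate_by_age:
    20: 0.008
    25: 0.01164
    30: 0.016936
    35: 0.024642
    40: 0.035854
    45: 0.052167
    50: 0.075902
    55: 0.110437
    60: 0.160684
    65: 0.233794
    70: 0.340169
    75: 0.494942
    80: 0.720137
    85: 1.047793
    90: 1.52453
    95: 2.218178
    100: 3.22743
  # Post-transplant mortality: baseline * max(1, 1.9 - 0.018*(band - 20)).
  # The multiplier exceeds 1 at younger ages (surgical and immunosuppression
  # risk against a low incident-dialysis baseline) and declines towards 1
  # with age; the net transplant survival advantage emerges over time as the
  # dialysis-exposure effect compounds in the comparator.
  post_transplant_death_rate_by_age:
    20: 0.0152
    25: 0.021068
    30: 0.02913
    35: 0.040166
    40: 0.055214
    45: 0.075642
    50: 0.103227
    55: 0.140254
    60: 0.189607
    65: 0.254836
    70: 0.340169
    75: 0.494942
    80: 0.720137
    85: 1.047793
    90: 1.52453
    95: 2.218178
    100: 3.22743
  # Exponential time-on-dialysis effect: rate multiplied by exp(0.15 * years).
  dialysis_time_coefficient: 0.15
  # Annual probability of dialysis withdrawal (death in the concurrent year).
  withdrawal_prob: 0.003
  # Proportion who never start renal replacement therapy.
  conservative_care_fraction: 0.02
  # Median years to a deceased-donor transplant; the annual transplant
  # probability is geometric-derived unless overridden below.
  median_wait: 4.5
  annual_transplant_prob: null
  # Annual graft failure (return to dialysis), by completed graft years;
  # graft ages beyond the last key use the last value.
  graft_failure_prob_by_graft_age:
    0: 0.07
    1: 0.03
    5: 0.025
  # Probability the transplant year is "complicated" (delayed graft
  # function, rejection, re-hospitalisation); affects costs only.
  perioperative_complication_prob: 0.30

costs:
  currency: AUD2008
  dialysis_initial:                 {mean: 76000.0,  se: 3800.0}
  dialysis_maintenance:             {mean: 45000.0,  se: 2250.0}
  transplant_initial_uncomplicated: {mean: 115000.0, se: 5750.0}
  transplant_initial_complicated:   {mean: 155000.0, se: 7750.0}
  transplant_maintenance:           {mean: 13500.0,  se: 675.0}
  comorbidity_annual_addon:
    none:           {mean: 0.0,    se: 0.0}
    cardiovascular: {mean: 6000.0, se: 300.0}
    diabetes:       {mean: 9000.0, se: 450.0}
    stroke:         {mean: 7000.0, se: 350.0}
    obesity:        {mean: 4000.0, se: 200.0}
    smoker:         {mean: 2500.0, se: 125.0}

config:
  discount_rate: 0.05
  cycle_length: 1.0
  half_cycle_correction: true
  cohort_size: 10000
  psa_iterations: 10000
  rng_seed: 1234
  max_age: 100
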