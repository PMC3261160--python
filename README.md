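# renalcea

A Markov cohort cost-effectiveness model comparing **waitlisting for
deceased-donor kidney transplantation** against **remaining on dialysis**
for people with end-stage kidney disease (ESKD), stratified by age at
listing and a single co-morbidity (cardiovascular disease, diabetes,
stroke, obesity, or current smoking).

It is aimed at health-economics and nephrology researchers who want a
tested, scriptable engine for listing-vs-dialysis decision questions:
expected life-years and discounted costs per strategy, incremental
cost-effectiveness ratios (ICERs) with dominance classification, one-way
and probabilistic sensitivity analyses, and age-by-waiting-time scenario
surfaces (including the unlimited-organ, zero-wait scenario).

## The model

A closed cohort enters the model on dialysis at a chosen age and is
followed in annual cycles until everyone has died. Under the *listing*
strategy, patients on the waitlist receive a deceased-donor transplant
with a constant annual probability `p = 1 − 2^(−1/m)` derived from the
median wait `m` (≈ 0.143/year for a 4.5-year median); under the
*not-listing* strategy they remain on dialysis. Recipients are
transplanted once; a failed graft returns the patient to dialysis until
death.

Mortality on dialysis compounds with exposure: the annual death rate is

```
r(age, d) = r0(age) · exp(γ · d) · HR(comorbidity)
```

where `d` is total years spent on dialysis (paused while a graft
functions), `r0` is an age-banded baseline, and `HR` is the adjusted
all-cause mortality hazard ratio for the co-morbidity. Death with a
functioning graft uses its own age-banded rate and hazard ratio. A small
fraction withdraws from dialysis each year (counted as death in the same
year), and a fraction never starts renal replacement therapy. Clock
dependence (dialysis exposure, graft age) is handled exactly by tunnel
expansion of the state space.

Costs attach per cycle (initial vs maintenance dialysis, complicated vs
uncomplicated transplant year, transplant maintenance, co-morbidity
add-ons). Life-years and costs are discounted at 5%/year with a
half-cycle correction, and strategies are compared by

```
ICER = (C_listing − C_dialysis) / (E_listing − E_dialysis)
```

reported only in the northeast quadrant of the cost-effectiveness plane
(dominant / dominated results suppress it). The probabilistic sensitivity
analysis samples hazard ratios from lognormal distributions (median at
the point estimate, spread from the 95% CI) and costs from
moment-matched gamma distributions.

Registry-grade inputs are not redistributable, so the package ships a
hand-calibrated **synthetic** default parameter set
(`renalcea.default_fixture()`, see `src/renalcea/data/default.yaml`) plus
a seeded generator for fixture families (`renalcea synth-params`). See
`docs/methods.md` for what the fixture does and does not emulate.

## Worked example

```
$ renalcea run --age 45 --comorbidity none --out results/
dE=0.773 LY, dC=7633, ICER=9878, tradeoff_ne, cost_effective
```

On the packaged fixture, listing a 45-year-old without co-morbidities
gains 0.77 discounted life-years at an extra discounted cost of $7,633,
an ICER of $9,878 per life-year saved — well under a $50,000/LYS
threshold, hence `cost_effective`. The run also writes
`cumulative_incremental.csv`; its `cum_delta_effect` column is negative
through the first few years (early post-transplant risk plus waiting-time
deaths) and turns positive at year 5 — the delayed-benefit crossover.

```
$ renalcea psa --age 45 --comorbidity diabetes --iterations 500 --seed 7 --out psa/
PSA n=500: mean dE=0.494, mean dC=14462, NE=99.8%
```

For a 45-year-old diabetic, nearly the whole Monte-Carlo cloud lies in
the northeast quadrant: listing is more effective *and* more costly, with
mean gain ≈ 0.49 life-years. `psa_scatter.csv` holds the per-iteration
(ΔE, ΔC) pairs for cost-effectiveness-plane plots.

Other subcommands: `renalcea scenario` (age × waiting-time grid,
`--waits 0,...` for the unlimited-organ scenario), `renalcea oneway`
(tornado-style single-parameter sweeps), `renalcea synth-params`
(seeded synthetic parameter files). Every command writes a JSON manifest
(parameter-file hash, seed, version, outputs) for reproducibility.

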