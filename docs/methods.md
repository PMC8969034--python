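# Methods

## Model structure

The simulator is a deterministic discrete-time Markov cohort model.  The
state space is the product of integer EDSS 0–9, treatment status (on /
off DMT) and sex (male / female), plus one absorbing dead state; the
cohort is a probability mass over these states, so every output is per
patient (the `cohort_size` field only rescales reported population
totals).  EDSS intermediates are rounded down to integers; EDSS 10
(death from MS) is not modelled separately but folded into the dead
state via the mortality hazard ratio.

The cycle length is fixed at one year and deliberately not configurable:
annualized relapse rates, annual cost inputs, annual discounting and the
10-year horizon then share a single, unambiguous time unit.

Each cycle proceeds as:

1. look up the active therapy from the scenario's segment list
   (half-open `[start, end)` segments; switches fall exactly on cycle
   boundaries);
2. record expected relapses from the start-of-cycle occupancy;
3. resolve death first: the annual background probability at the
   cohort's integer age, per sex, multiplied by the MS mortality hazard
   ratio (default 1.7), identical for every living EDSS state and for
   both treatment statuses;
4. move the survivors through the (treatment-adjusted) EDSS matrix;
5. move on-DMT mass at EDSS > 6 off DMT (irreversibly);
6. age the cohort by one year.

Valuation is start-of-cycle throughout — costs, YLD, informal-care days
and relapses accrue from the state occupied at the beginning of each
year, with no half-cycle correction.  Recording relapses from the
start-of-cycle state (step 2, before the transition) keeps the relapse
process consistent with that convention; the alternative (recording from
the post-transition state) would price relapses against a state the
cohort only reaches at the end of the year.

### Treatment effects

A therapy carries a hazard ratio `h` from 6-month confirmed disability
progression and a relapse rate ratio `r`.  The hazard ratio is applied
to every worsening entry of the natural-history matrix on the
complementary-log scale, `p' = 1 − (1 − p)^h`, which is exactly
equivalent to multiplying the implied constant per-cycle hazard by `h`
(`rate_to_prob(h · prob_to_rate(p))`).  The probability mass freed by
reduced worsening is added to the stay probability; improvement
transitions are left at natural-history values.  Adjusting worsening
only reflects that the effect estimate concerns disability
*progression*; whether improvement should also be adjusted is unknown,
and the worsening-only choice is the conservative reading.  A useful
consequence: a lower hazard ratio produces first-order stochastic
dominance of the EDSS distribution at every cycle, which the test suite
verifies and which guarantees the monotone scenario orderings reported
by the outcome layer.

With `h > 1` on a row whose worsening mass nearly exhausts the stay
probability, the freed-mass bookkeeping would drive the stay entry
negative; the engine rejects such inputs explicitly rather than
clipping.  This cannot occur for efficacy hazard ratios below 1 or for
stay-dominant matrices.

Off-DMT strata evolve under a built-in inert "none" effect (hazard and
rate ratios 1, zero cost).  Discontinuation is irreversible: mass that
improves back to EDSS ≤ 6 stays off DMT.  The model imputes no separate
adverse-event discontinuation and no waning of effect.

### Mortality, YLL, YLD

Mortality is independent of EDSS and treatment: one age/sex life table
times one uniform hazard ratio.  A direct structural consequence is that
the death trajectory — and therefore YLL — is identical across all
treatment-sequencing scenarios; the acceptance suite checks this to
1e-10.  YLL weights the deaths of each cycle by the remaining
general-population life expectancy at the integer age and sex of death
and discounts them at the effects rate.  YLD weights living state-years
by per-EDSS disability weights, discounted likewise; `DALY = YLL + YLD`
is computed as the exact sum of the two terms.  Relapse counts and
years-in-band are reported undiscounted, in natural units; years-in-band
counts cycle boundaries 1..horizon so that a full-horizon stay equals
the horizon length.

Snapshot outcomes (band shares, mean EDSS, employment / full-time /
invalidity shares) are read at the final cycle and normalized over
survivors, so the four disability bands sum to 100%.  Productivity
shares are defined only while the cohort is below retirement age
(default 67); a cohort past retirement reports zero shares with an
explicit flag.

### Costs

All costs are in a single abstract currency unit (documented as EUR),
discounted at 3%/year by `(1 + r)^-t` with `t` the 0-based cycle index.
Drug prices distinguish the first year on a therapy (loading doses) from
subsequent years, keyed to time since that therapy's initiation *within
the scenario* — required so a mid-horizon switch prices the new
therapy's first year correctly.  An optional explicit second-year price
field exists so the three standard price factors of the sensitivity
analysis (year 1, year 2, year 2 onwards) each map to one input; it
defaults to the subsequent-year price.  One knock-on convention: a
sequence that lists the same therapy in two adjacent segments re-prices
its year-1 cost at the second segment's start, so a single continuous
segment should be used per therapy.

Indirect costs are modelled as two per-EDSS annual productivity-loss
inputs (short-term absence; long-term absence / invalidity / early
retirement) rather than a wage × employment microdata model, keeping the
accounting transparent; the employment shares themselves are reported by
the outcome layer.  Relapse costs (expected relapses × 2,662 €) are
estimated separately and *added* to the direct + indirect sum; since the
per-state cost inputs may already cover part of the relapse burden, the
grand total is an acknowledged overestimate, and the report carries that
note.  Percentage shares use each subtotal as denominator for its
categories, and the direct + indirect sum for the subtotals and the
relapse line; rounding happens only at presentation.

### Sensitivity analysis

One-way ±10% perturbations, each from an independent copy of the base
parameter set, rerunning both scenarios of the pair; the default metric
is incremental discounted total cost (comparator minus reference).  Nine
factors: the three OMB price points, the OMB progression hazard ratio,
cohort size, start age, male fraction, both discount rates jointly, and
the relapse unit cost.  Cohort size is a documented no-op on per-patient
metrics; perturbed proportions are clamped to [0, 1] with a recorded
note.  Results are sorted by range (tornado order).

## Synthetic inputs

The generator emulates the structure of the study's input tables with
one seeded `numpy.random.Generator`:

* **Baseline.**  A normal distribution (SD 1.2) truncated to [0, 7) and
  floor-discretized onto EDSS 0–6; the continuous mean is calibrated by
  root-finding so the discretized mean hits the target 2.3 exactly.
  Start age 36.3, 33% male.
* **Natural history.**  A banded matrix: stay ≈ 0.72, one-step worsening
  ≈ 0.17, two-step ≈ 0.03, improvement ≈ 0.06 / 0.01, each jittered
  ±15% per seed, remainder on the diagonal.  Worsening exceeds
  improvement in every row except the top state, which cannot worsen
  (there it keeps a token 3% improvement).  Out-of-range two-step moves
  fold into the nearest feasible move.
* **Relapse rates.**  0.7/year for EDSS ≤ 4, 0.5/year above, exactly.
* **Treatment effects.**  Progression hazard ratios 0.41 (OMB), 0.73
  (DMF), 0.85 (GA) and relapse rate ratios 0.25 / 0.53 / 0.66 —
  placebo-referenced magnitudes typical of network meta-analyses of
  these drug classes, with the high-efficacy therapy strictly superior.
  Prices 20,000 € (year 1) / 18,000 € (OMB), 13,000 € (DMF), 9,000 €
  (GA): the superior drug is the costlier one.
* **Mortality.**  Gompertz hazards `q(a) = A·e^{0.093a}` with male
  excess (`A` = 3.2e-5 vs 1.7e-5), closed at age 110; remaining
  (curtate) life expectancy is computed from the same table, so the two
  are mutually consistent.  MS hazard ratio 1.7.
* **Valuations.**  Per-EDSS disability weights, eight direct-cost
  categories, informal-care days, employment fractions and two indirect
  cost series.  Levels around EDSS 2–3 are set so that a 10-year
  discounted accumulation on an early-RMS trajectory lands near
  published German per-category sums, with mild-to-bedridden gradients
  of roughly 3–10× (informal care steeper) as in the MS cost-of-illness
  literature.  Jitter is one multiplicative factor per series (±8%), so
  every monotonicity constraint — costs, weights, days and invalidity
  rising in EDSS; employment and full-time falling; short-term absence
  falling (it tracks employment) — holds for every seed, which a
  100-seed property test enforces.

What the generator does **not** emulate: the real British Columbia
transition probabilities (only their band structure), the actual trial
EDSS histogram (only its mean/SD), German life-table values (only
Gompertz shape and male excess), correlations between cost categories,
and any heterogeneity within an EDSS state.  Passing tests on synthetic
sets therefore demonstrate structural and qualitative properties —
conservation, dominance, sign patterns, accounting identities — not
numeric agreement with any published cohort.

## Numerical choices

* Row-sum validation tolerance 1e-12 on constructed objects; the file
  loader renormalizes rows off by ≤ 1e-9 and rejects anything worse,
  naming the row.
* Mass conservation is asserted at every cycle to 1e-10.
* Age is floored to an integer for life-table lookup; the cohort ages
  deterministically from its mean start age (age heterogeneity is not
  propagated; the start-age sensitivity factor covers it).
* Parameter CSVs are written with `%.17g` and read with round-trip
  float parsing, so save → load reproduces a parameter set bit-exactly.
* Degenerate inputs (probability ≥ 1 under a hazard ratio ≠ 1, negative
  rates, ages outside the life table, empty survivor sets) raise
  immediately rather than propagating NaNs.

## Problem sizes

The bundled analyses run at the study's natural scale: 10 annual cycles,
40 living strata plus death, four scenarios, and 100-seed property
sweeps; the whole test suite and the acceptance script each complete in
seconds.

## Known limitations

* Constant transition probabilities and treatment effects over time; no
  waning, no response-dependent (escalation-triggered) switching.
* Relapses do not feed back into EDSS dynamics.
* No probabilistic sensitivity analysis; the one-way tornado is the only
  uncertainty quantification.
* No payer-perspective split of direct costs, no currency-year
  adjustment, no QALYs (the analysis is a CCA by design).
* Mortality independent of EDSS is a modelling assumption inherited from
  the uniform hazard ratio; with EDSS-dependent mortality the zero-YLL
  property would not hold.
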