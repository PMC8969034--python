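# mscca

An EDSS-based Markov cohort simulator and cost-consequence analysis (CCA)
of treatment-sequencing strategies in relapsing multiple sclerosis (RMS),
from a societal perspective.

## The problem

Highly effective disease-modifying therapies (DMTs) such as the anti-CD20
antibody ofatumumab (OMB) are usually reserved for patients who fail a
standard therapy (dimethyl fumarate, DMF, or glatiramer acetate, GA).
Whether to start the high-efficacy drug immediately, switch to it after
one year, after five years, or never, is both a clinical and an economic
question: the drug is more expensive, but slower disability accumulation
reduces care needs and productivity loss.  This package simulates those
four sequencing scenarios over a 10-year horizon and lists their clinical
consequences and discounted societal costs side by side — a CCA, with no
cost-per-outcome ratio.

## The model

The cohort is propagated over discrete health states given by the integer
Expanded Disability Status Scale, EDSS 0–9 (intermediate scores rounded
down), stratified by sex and treatment status, plus an absorbing dead
state.  With one-year cycles, the per-cycle risks are:

* **EDSS transition.**  An annual natural-history matrix `P` gives
  untreated probabilities of worsening, improvement or stable EDSS.  An
  active DMT modifies each worsening entry through its hazard ratio `h`
  for 6-month confirmed disability progression on the complementary-log
  scale, `p' = 1 − (1 − p)^h`, with the freed mass added to the stay
  probability; improvement is untouched.
* **Death.**  Background age/sex mortality `q(a, s)` times a single MS
  mortality hazard ratio (1.7), identical for every living state; death
  is resolved first, EDSS moves are conditional on survival.
* **Relapse.**  A parallel counting process: state-dependent annualized
  relapse rates (≈0.7 for EDSS ≤ 4, ≈0.5 above), multiplied by the active
  DMT's relapse rate ratio.
* **Treatment discontinuation.**  Mass reaching EDSS > 6 stops DMT
  irreversibly and reverts to natural-history dynamics.

Outcomes per scenario: the EDSS distribution and its disability bands
(0–3 mild, 4–6 walking aid, 7 wheelchair, 8–9 bedridden), mean EDSS over
time, years per band, expected relapses, informal-care days, employment /
full-time / invalidity-pension shares, and disability-adjusted life years
`DALY = YLL + YLD`, where YLL weights deaths by remaining age/sex life
expectancy and YLD weights living state-years by per-EDSS disability
weights.  Costs per patient (EUR, discounted at 3%/year) cover drug
acquisition (year-1 vs subsequent pricing relative to each therapy's
initiation), eight non-DMT direct categories, two indirect
productivity-loss categories (below retirement age 67), and separately
estimated relapse costs (2,662 € per relapse).  A one-way ±10% tornado
analysis perturbs nine standard factors.

Because the original per-EDSS input tables are not redistributable, the
package includes a seeded synthetic generator that reproduces their
structure (baseline EDSS mean 2.3 ± 1.2 on 0–6, age 36.3, 33% male,
stay-dominant transition bands, costs rising and employment falling in
EDSS); real inputs can be supplied through the same file format.

## Worked example

```python
import mscca

params = mscca.generate_parameter_set(mscca.SyntheticConfig(seed=1))
for spec in mscca.builtin_scenarios("DMF"):
    trace = mscca.run_scenario(params, spec)
    out = mscca.build_outcome_report(trace, params)
    cost = mscca.compute_cost_report(trace, params, spec)
    print(
        f"{spec.label:22s}  mean EDSS {out.mean_edss_by_year[-1]:.2f}  "
        f"relapses {out.total_relapses:.2f}  DALYs {out.daly:.2f}  "
        f"employed {100 * out.employed_share:.1f}%  "
        f"DMT EUR {cost.direct['dmt']:,.0f}  total EUR {cost.total:,.0f}"
    )
```

prints

```
Base-Scenario (10/0)    mean EDSS 2.56  relapses 1.73  DALYs 1.78  employed 58.6%  DMT EUR 158,123  total EUR 317,376
Scenario A (1/9)        mean EDSS 2.63  relapses 1.92  DALYs 1.81  employed 58.0%  DMT EUR 152,808  total EUR 316,169
Scenario B (5/5)        mean EDSS 2.91  relapses 2.70  DALYs 1.90  employed 55.7%  DMT EUR 133,018  total EUR 309,018
Base-Scenario (0/10)    mean EDSS 3.26  relapses 3.60  DALYs 1.94  employed 52.7%  DMT EUR 111,331  total EUR 293,378
```

Read across the rows: the later the switch to the high-efficacy therapy,
the higher the final mean EDSS, the more relapses and DALYs, and the
lower the employment share — while drug costs fall and care/productivity
costs rise, leaving totals within a few percent of each other.  (The
DALY column is higher under every scenario than YLD alone because it
includes ~0.60 years of life lost, which is identical across scenarios:
mortality does not depend on EDSS or treatment.)

The same comparison is available from the shell:

```bash
mscca generate --seed 1 --out params/         # write synthetic inputs
mscca compare --params params/parameters.yaml --out results/
mscca sensitivity --seed 1 --out results/     # tornado table
```

## Layout

| module | contents |
| --- | --- |
| `mscca.parameters` | input types, validation, YAML+CSV I/O, probability/hazard transforms |
| `mscca.synthetic` | seeded synthetic parameter sets and the hand-written worked fixture |
| `mscca.scenarios` | treatment sequences and the four built-in scenarios |
| `mscca.engine` | the Markov cohort engine |
| `mscca.outcomes` | EDSS bands, relapses, DALY/YLL/YLD, productivity, informal care |
| `mscca.costs` | discounted cost accumulation and report identities |
| `mscca.sensitivity` | one-way ±10% tornado analysis |
| `mscca.reporting` / `mscca.cli` | comparison bundles, writers, command line |

Methodological details and design choices are documented in
[docs/methods.md](docs/methods.md).
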