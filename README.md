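# ckdcea

A Markov cohort model for the cost-effectiveness of **intensive versus
standard hypertension control in hypertensive chronic-kidney-disease (CKD)
patients**, written for health-economics analysts who want a scriptable,
testable alternative to spreadsheet/TreeAge decision models.

Patients aged 50+ start in a healthy hypertensive-CKD state and move each
year between eleven states: healthy, six acute serious-adverse-event (SAE)
states attributable to antihypertensive treatment (hypotension, syncope,
bradycardia, electrolyte abnormality, injurious fall, acute renal failure),
three chronic cardiovascular-disease (CVD) states (myocardial infarction,
stroke, heart failure), and death. Each state carries an annual cost
(USD/person/year, converted at 1,180 KRW/USD) and a utility weight
(QALY/year). The intensive arm (target 120/80 mmHg vs 140/90 mmHg) modifies
the baseline annual probabilities through published hazard ratios and incurs
1.2× the healthy-state outpatient cost.

For a cohort starting at age *a₀* the model iterates annual cycles
*t = 0, 1, …* with row-stochastic transition matrices *P(a₀+t)*, accruing

> C = Σₜ (1+r)⁻ᵗ · xₜᵀ c(a₀+t)  and  E = Σₜ (1+r)⁻ᵗ · xₜᵀ u

where *xₜ* is the state-occupancy vector, *c* the state cost vector, *u* the
utility vector and *r* the annual discount rate (5% base case). The decision
metric is the incremental cost-effectiveness ratio
**ICER = ΔC/ΔE** (intensive minus standard), judged against a
willingness-to-pay threshold of 31,362.80 USD/QALY (2019 Korean GDP per
capita), with full dominance / extended-dominance classification.

Competing annual risks from the healthy state are combined on the rate scale
(rᵢ = −ln(1−pᵢ), total event probability 1−e^(−Σrᵢ), allocated ∝ rᵢ), and
hazard ratios are applied as p → 1−(1−p)^HR. An individual-level
microsimulation of the same chain serves as an independent Monte-Carlo check
of the cohort recursion.

## Worked example

The bundled default configuration pins a complete parameter set: published
hazard ratios and utilities, and age curves expanded deterministically from
the published (low, high) ranges (incidence/mortality linear over ages
50–100, costs at range midpoints).

```python
from ckdcea import default_bundle, evaluate_bundle

result = evaluate_bundle(default_bundle())
print(result.to_dataframe().round(2).to_string(index=False))
```

```
intervention     cost  incremental_cost  effectiveness  incremental_effectiveness    icer  cost_per_effectiveness   dominance
    standard 84602.72               NaN          14.60                        NaN     NaN                 5792.76 undominated
   intensive 87704.79           3102.08          15.05                       0.44 6988.21                 5828.02 undominated
```

Read: over a lifetime horizon discounted at 5%, standard control accrues
84,602.7 USD and 14.60 QALYs per patient, intensive control 87,704.8 USD and
15.05 QALYs. Both strategies are undominated; intensive control buys its
extra 0.44 QALYs at 6,988.2 USD/QALY — well below the 31,362.80 USD/QALY
threshold, so `result.cost_effective_at_wtp` is `True`. The conclusion is
unchanged at 3% and 7% discounting (ICERs 7,587.9 and 6,509.4 USD/QALY).

The same pipeline is available from the shell:

```bash
ckdcea run --out out/                 # traces, CEA table, CE plane, manifest
ckdcea sensitivity --out out/         # discount-rate scenarios (3/5/7%)
ckdcea tornado --out out/             # one-way hazard-ratio tornado
ckdcea synth --seed 7 --mode range_sample --out synth.yaml
```

`synth` writes a synthetic parameter set in the same config dialect `run`
reads, so every stage is exercisable without any data access.

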