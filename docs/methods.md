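# Methods

## Model

A discrete-time Markov cohort model with 1-year cycles over hypertensive
CKD patients aged 50 or older. Eleven states: one healthy hypertensive-CKD
state, six acute SAE states (hypotension, syncope, bradycardia, electrolyte
abnormality, injurious fall, acute renal failure), three chronic CVD states
(MI, stroke, heart failure), and absorbing death.

Transitions, per cycle at age *a*:

- **From healthy**: nine event risks (the six SAEs and three CVDs) plus
  background hypertension mortality compete. Each annual probability is
  converted to a constant rate rᵢ = −ln(1−pᵢ); the total event probability
  is 1−exp(−Σrᵢ), allocated across events proportionally to rᵢ; the
  remainder stays healthy. This keeps the row valid even when Σpᵢ > 1
  (the injurious-fall incidence alone is ~35%/year). A naive direct-sum
  allocation is available via `model.competing_risk_method: direct_sum` for
  comparison; it errors once probabilities sum past one.
- **From an SAE state**: die with that event's annual mortality, otherwise
  return to healthy — SAE states are one-cycle tunnels, reflecting acute
  drug-related events whose reduced utility (0.60) applies only during the
  event year. `model.sae_persistent: true` makes them chronic instead.
- **From a CVD state**: die with that CVD's annual mortality, otherwise
  remain. No further event incidence is modelled from CVD states
  (parsimony). MI mortality is published as 0% and is taken literally, so
  the MI state can only be left by the model horizon.
- **Death** is absorbing.

The intensive arm applies hazard ratios through the rate transform
p → 1−(1−p)^HR (default; the ratios come from survival models), or
optionally p → min(p·HR, 1). Per-event ratios apply to incidence only;
mortality inside CVD states uses the CVD-death ratio (0.57), background and
SAE mortality use the non-CVD-death ratio (0.72). The published aggregate
disease-events ratio (0.94) is carried in the configuration for completeness
but is inert in the transition model. The intensive arm also multiplies the
healthy-state annual cost by 1.2 — the published factor for extra outpatient
use. Because the cost table does not split inpatient from outpatient
spending, the multiplier is applied to the whole healthy-state cost; an
approximation, defensible because hypertension maintenance cost is
outpatient-dominated.

## Accrual and discounting

Cycle *t* (t = 0, 1, …) values the start-of-cycle occupancy at that cycle's
age: cost Σₛ xₜ(s)·c(s, a₀+t)·mult(s) and QALYs Σₛ xₜ(s)·u(s), each
discounted by (1+r)⁻ᵗ, so cycle 0 is undiscounted. The run stops at
`max_age` (default 100 — a conventional lifetime horizon; survival beyond
it is negligible for decision purposes) or when the live fraction drops
below 1e-9. No half-cycle correction is applied by default (matching the
common TreeAge default); `economics.half_cycle_correction: true` averages
start- and end-of-cycle occupancy instead.

All arithmetic is in USD (KRW accepted at input only, at the fixed 1,180
KRW/USD study rate) and is carried unrounded; only the reporting layer
rounds (one decimal for money, two for QALYs), which is why ratios of
published rounded cells differ slightly from published ICERs.

## Parameters

Defaults (bundled config `ckdcea/data/default.yaml`):

- annual incidence/mortality probabilities and annual per-state USD costs,
  age dependent over 50–100, published as (low, high) ranges;
- utilities (QALY/year): hypertension 1.00, MI 0.70, stroke 0.65, HF 0.64,
  any SAE 0.60, death 0;
- hazard ratios with 95% CIs as published;
- discount rate 0.05/year, WTP threshold 31,362.80 USD/QALY, cohort size
  72,429 (used by the microsimulation), start age 50.

The source never states which ages the printed range endpoints belong to.
The package's convention: the low endpoint at the youngest age, rising
linearly to the high endpoint at `max_age` (risks in this population rise
with age; linear is the simplest monotone form). Costs use range midpoints
in the pinned default, since cost-age profiles are less plausibly monotone.
These conventions are the package's own and are the main reason model totals
are comparable to the published ones only in order of magnitude and decision
direction, not cell by cell.

## Synthetic generation

`synthetic.generate_param_set` emulates the unavailable claims-derived
estimates. Modes: `default` (the pinned bundle above; deterministic),
`midpoint` (every curve constant at its range midpoint), `range_sample`
(both endpoints of each curve drawn uniformly inside its printed range from
a generator seeded once per call; linear in between). Optional
multiplicative Gaussian jitter (`noise_sd_frac`) is clipped back into the
printed range and, for probabilities, into [0, 1]. Cohort starting ages are
drawn from a configurable distribution, uniform over 50–79 by default (the
source population is described only as "aged 50 or older").

What the generator does *not* emulate: covariates other than age, secular
trends, correlation between incidence and cost curves, and sampling noise in
the original estimation. Passing tests therefore demonstrate correctness of
the decision machinery on parameter sets consistent with the published
ranges — not agreement with the unpublished age-specific estimates.

## Incremental analysis and dominance

The reference arm is pinned to `standard` (the cheaper arm in the base
case). Keeping it fixed across sensitivity runs keeps ΔC/ΔE signs and ICERs
comparable; when a sensitivity run makes the intensive arm cheaper *and*
more effective it is reported as DOMINANT rather than silently re-basing.
ICER sentinels: DOMINANT (ΔC<0, ΔE>0), DOMINATED (ΔC>0, ΔE<0), UNDEFINED
(ΔE=0); ΔC=0 with ΔE>0 is a free gain (ICER 0). The decision rule is
ICER ≤ WTP, with DOMINANT accepted and DOMINATED/UNDEFINED rejected.
Dominance classification applies strict dominance first, then iterative
extended dominance on the effect-ordered frontier; exactly equal points are
both kept (weak dominance is not applied).

## Sensitivity analyses

Discount-rate scenarios re-run the full pipeline per rate (default 3/5/7%).
The tornado varies each of the 12 hazard ratios across its 95% CI, all else
at base case, and sorts bars by descending ICER swing |ICER_high−ICER_low|.
Cost and utility ranges are excluded from the default tornado because no
interval estimates are published for them. An endpoint whose ICER hits a
dominance sentinel is plotted at 0 with the sentinel recorded — this keeps
swings finite but makes such bars' swings an artefact of the plotting
convention, which matters when ranking bars (the stroke ratio's lower CI
makes the intensive arm dominant on the default bundle, giving that bar the
top rank). The aggregate disease-events ratio yields a structural zero-swing
bar, a useful inertness check.

## Numerical choices

- Transition rows validated to sum to 1 within 1e-12; occupancy to 1 within
  1e-9 per cycle; death occupancy non-decreasing.
- Cohort termination threshold 1e-9 live fraction.
- Rate-based competing risks reject any single annual probability of
  exactly 1 (infinite rate); the direct-sum method accepts it.
- The microsimulation samples transitions by inverse CDF on each row with
  one seeded generator per call; two calls with the same seed are
  bit-identical.
- Problem sizes: 51 annual cycles (ages 50–100); microsimulation checks use
  the full 72,429-patient cohort size; property suites use 100 seeded
  random bundles.

## Known limitations

- Age is the only covariate; no treatment switching, adherence, BP
  trajectories, or recurrent CVD events.
- CVD states with near-zero published mortality (MI at 0%) act as low-risk
  absorbing harbors, which can make event prevention look QALY-costly in
  extreme sensitivity scenarios; this is a faithful consequence of the
  printed inputs plus the minimal topology, not a claim about clinical
  reality.
- No probabilistic sensitivity analysis (none was performed in the source
  evaluation); the config schema deliberately leaves room for parameter
  distributions as an extension.
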