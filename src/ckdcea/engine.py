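"""Markov cohort engine: transition matrices, annual-cycle cohort traces,
and an individual-level microsimulation oracle.

Model topology
--------------
From the healthy hypertensive-CKD state a patient may, each year, suffer one
of nine events (six acute serious adverse events, three cardiovascular
diseases) or die of background hypertension mortality; the competing annual
probabilities are combined on the rate scale (r_i = -ln(1 - p_i), total event
probability 1 - exp(-sum r_i), allocated proportional to r_i), which yields a
valid transition row even when the probabilities sum past one. SAE states are
one-cycle tunnels — survivors return to healthy after the event year. CVD
states are chronic: patients remain until death. Death is absorbing.

The intensive arm applies each event's hazard ratio to the corresponding
baseline incidence, the CVD-death hazard ratio to mortality inside CVD
states, and the non-CVD-death hazard ratio to background and SAE mortality,
by default through the rate transform p -> 1 - (1 - p)^HR.

Accrual and discounting: cycle t (t = 0, 1, ...) values the start-of-cycle
occupancy at the cycle's age and discounts by (1 + r)^-t, so cycle 0 is
undiscounted. No half-cycle correction is applied unless enabled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError, ModelConstructionError
from .parameters import (
    CVD_NAMES,
    DEATH,
    EVENT_NAMES,
    HEALTHY,
    SAE_NAMES,
    STATE_ORDER,
    CompetingRiskMethod,
    EconomicConfig,
    HRApplication,
    ParameterBundle,
    StrategySpec,
)

N_STATES = len(STATE_ORDER)
_IDX = {s: i for i, s in enumerate(STATE_ORDER)}
_HEALTHY_I = _IDX[HEALTHY]
_DEATH_I = _IDX[DEATH]

LIVE_EPS = 1e-9  # cohort fraction below which the simulation stops


def adjust_probability(p: float, hr: float,
                       method: HRApplication | str = HRApplication.RATE_TRANSFORM) -> float:
    """Apply a hazard ratio to an annual probability.

    ``rate_transform`` maps through the constant-rate scale,
    ``1 - (1 - p)^hr``, which stays in [0, 1] for any hr > 0;
    ``probability_multiply`` is the naive ``min(p * hr, 1)``. The two agree
    to first order as p -> 0.
    """
    if not (0.0 <= p <= 1.0):
        raise DomainError(f"probability must lie in [0, 1], got {p}")
    if hr <= 0:
        raise DomainError(f"hazard ratio must be > 0, got {hr}")
    method = HRApplication(method)
    if method is HRApplication.RATE_TRANSFORM:
        return 1.0 - (1.0 - p) ** hr
    return min(p * hr, 1.0)


def _arm_probability(bundle: ParameterBundle, strategy: StrategySpec,
                     curve_name: str, hr_target: str | None, age: float) -> float:
    p = bundle.curve(curve_name).value_at(age)
    if hr_target is None:
        return p
    hr = strategy.hr_point(hr_target)
    if hr == 1.0:
        return p
    return adjust_probability(p, hr, strategy.hr_application)


def build_transition_matrix(age: float, strategy: StrategySpec,
                            bundle: ParameterBundle) -> np.ndarray:
    """One-cycle transition matrix at ``age`` under ``strategy``.

    Rows/columns follow :data:`~ckdcea.parameters.STATE_ORDER`. Rows are
    row-stochastic; the death row is the identity row.
    """
    M = np.zeros((N_STATES, N_STATES))

    # Healthy row: nine event risks plus background mortality compete.
    probs = [_arm_probability(bundle, strategy, f"incidence_{ev}", ev, age)
             for ev in EVENT_NAMES]
    p_die = _arm_probability(bundle, strategy, "mortality_hypertension",
                             "non_cvd_death", age)
    probs.append(p_die)
    dests = [_IDX[ev] for ev in EVENT_NAMES] + [_DEATH_I]
    p = np.asarray(probs)
    if bundle.competing_risk_method is CompetingRiskMethod.RATE_BASED:
        if np.any(p >= 1.0):
            raise ModelConstructionError(
                "an annual probability of 1 admits no competing-risk rate")
        rates = -np.log1p(-p)
        total_rate = rates.sum()
        if total_rate > 0:
            total_event = -np.expm1(-total_rate)
            alloc = total_event * rates / total_rate
        else:
            alloc = np.zeros_like(rates)
        stay = np.exp(-total_rate)
    else:  # direct sum, valid only while probabilities sum below 1
        if p.sum() > 1.0:
            raise ModelConstructionError(
                f"competing probabilities sum to {p.sum():.4f} > 1 at age {age}; "
                "use the rate_based method")
        alloc = p
        stay = 1.0 - p.sum()
    M[_HEALTHY_I, _HEALTHY_I] = stay
    for dest, a in zip(dests, alloc):
        M[_HEALTHY_I, dest] += a

    # SAE rows: die of the event's mortality, otherwise the tunnel empties
    # back to healthy (or the state persists if configured chronic).
    for name in SAE_NAMES:
        i = _IDX[name]
        q = _arm_probability(bundle, strategy, f"mortality_{name}",
                             "non_cvd_death", age)
        M[i, _DEATH_I] = q
        M[i, _IDX[name] if bundle.sae_persistent else _HEALTHY_I] = 1.0 - q

    # CVD rows: chronic until death; CVD-death hazard ratio applies.
    for name in CVD_NAMES:
        i = _IDX[name]
        q = _arm_probability(bundle, strategy, f"mortality_{name}",
                             "cvd_death", age)
        M[i, _DEATH_I] = q
        M[i, i] = 1.0 - q

    M[_DEATH_I, _DEATH_I] = 1.0

    rowsum = M.sum(axis=1)
    if not np.allclose(rowsum, 1.0, rtol=0, atol=1e-12):
        raise ModelConstructionError(f"rows do not sum to 1: {rowsum}")
    return M


def state_cost_vector(age: float, strategy: StrategySpec,
                      bundle: ParameterBundle) -> np.ndarray:
    """Annual USD cost of each state at ``age``; the healthy-state cost
    carries the strategy's outpatient multiplier."""
    c = np.zeros(N_STATES)
    c[_HEALTHY_I] = (bundle.curve("cost_hypertension").value_at(age)
                     * strategy.healthy_cost_multiplier)
    for name in EVENT_NAMES:
        c[_IDX[name]] = bundle.curve(f"cost_{name}").value_at(age)
    return c


@dataclass
class CohortTrace:
    """Per-cycle record of a cohort run.

    ``occupancy[t]`` is the state distribution at the start of cycle ``t``
    (fractions summing to 1); increments are per-cycle cost (USD) and QALY
    accruals, undiscounted and discounted.
    """

    strategy: str
    ages: np.ndarray
    occupancy: np.ndarray
    cost: np.ndarray
    qaly: np.ndarray
    cost_disc: np.ndarray
    qaly_disc: np.ndarray

    @property
    def total_cost(self) -> float:
        return float(self.cost.sum())

    @property
    def total_qaly(self) -> float:
        return float(self.qaly.sum())

    @property
    def total_cost_disc(self) -> float:
        return float(self.cost_disc.sum())

    @property
    def total_qaly_disc(self) -> float:
        return float(self.qaly_disc.sum())

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy,
                          columns=[f"occ_{s}" for s in STATE_ORDER])
        df.insert(0, "age", self.ages)
        df.insert(0, "cycle", np.arange(len(self.ages)))
        df["cost"] = self.cost
        df["qaly"] = self.qaly
        df["cost_disc"] = self.cost_disc
        df["qaly_disc"] = self.qaly_disc
        return df


def run_cohort(start_age: int, strategy: StrategySpec, bundle: ParameterBundle,
               economics: EconomicConfig | None = None) -> CohortTrace:
    """Run the annual-cycle cohort simulation from ``start_age``.

    Cycles run while the cohort age does not exceed ``max_age`` and the
    surviving fraction stays above ``LIVE_EPS``; totals are the sums of the
    per-cycle increments.
    """
    eco = economics if economics is not None else bundle.economics
    if start_age < 50:
        raise DomainError(f"start_age {start_age} below model minimum of 50")
    if start_age > eco.max_age:
        raise DomainError(f"start_age {start_age} exceeds max_age {eco.max_age}")
    util = bundle.utilities.vector()
    r = eco.discount_rate

    occ = np.zeros(N_STATES)
    occ[_HEALTHY_I] = 1.0

    ages, occs, costs, qalys, costs_d, qalys_d = [], [], [], [], [], []
    t = 0
    while True:
        age = start_age + t
        live = 1.0 - occ[_DEATH_I]
        if age > eco.max_age or live < LIVE_EPS:
            break
        cvec = state_cost_vector(age, strategy, bundle)
        if eco.half_cycle_correction and age < eco.max_age:
            M = build_transition_matrix(age, strategy, bundle)
            occ_val = 0.5 * (occ + occ @ M)
        else:
            M = None
            occ_val = occ
        cost_t = float(occ_val @ cvec)
        qaly_t = float(occ_val @ util)
        disc = (1.0 + r) ** (-t)
        ages.append(age)
        occs.append(occ.copy())
        costs.append(cost_t)
        qalys.append(qaly_t)
        costs_d.append(cost_t * disc)
        qalys_d.append(qaly_t * disc)
        if M is None:
            M = build_transition_matrix(age, strategy, bundle)
        occ = occ @ M
        t += 1

    return CohortTrace(
        strategy=strategy.name,
        ages=np.asarray(ages),
        occupancy=np.asarray(occs),
        cost=np.asarray(costs),
        qaly=np.asarray(qalys),
        cost_disc=np.asarray(costs_d),
        qaly_disc=np.asarray(qalys_d),
    )


def run_strategy_pair(bundle: ParameterBundle,
                      economics: EconomicConfig | None = None
                      ) -> tuple[CohortTrace, CohortTrace]:
    """Run both arms on identical baseline parameters; only hazard ratios and
    the healthy-state cost multiplier differ."""
    eco = economics if economics is not None else bundle.economics
    std = run_cohort(eco.start_age, bundle.strategies["standard"], bundle, eco)
    inten = run_cohort(eco.start_age, bundle.strategies["intensive"], bundle, eco)
    return std, inten


def microsim_oracle(bundle: ParameterBundle, economics: EconomicConfig | None,
                    strategy: StrategySpec, n: int, seed: int
                    ) -> dict[str, float]:
    """Monte-Carlo microsimulation of ``n`` individual trajectories.

    Samples transitions from the same matrices the cohort model uses; the
    cohort trace is the exact expectation of this process, so for large ``n``
    the means must fall within a few standard errors of the cohort totals.
    Returns discounted means and their standard errors.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    eco = economics if economics is not None else bundle.economics
    rng = np.random.default_rng(seed)
    util = bundle.utilities.vector()
    r = eco.discount_rate

    states = np.full(n, _HEALTHY_I, dtype=np.int64)
    cost_acc = np.zeros(n)
    qaly_acc = np.zeros(n)
    t = 0
    while True:
        age = eco.start_age + t
        alive = states != _DEATH_I
        if age > eco.max_age or not alive.any():
            break
        cvec = state_cost_vector(age, strategy, bundle)
        disc = (1.0 + r) ** (-t)
        cost_acc += disc * cvec[states]
        qaly_acc += disc * util[states]
        M = build_transition_matrix(age, strategy, bundle)
        cum = np.cumsum(M, axis=1)
        u = rng.random(n)
        new_states = states.copy()
        for s in np.unique(states):
            if s == _DEATH_I:
                continue
            mask = states == s
            new_states[mask] = np.searchsorted(cum[s], u[mask], side="right")
        states = np.minimum(new_states, N_STATES - 1)
        t += 1

    return {
        "mean_cost": float(cost_acc.mean()),
        "mean_qaly": float(qaly_acc.mean()),
        "se_cost": float(cost_acc.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "se_qaly": float(qaly_acc.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        "n": n,
    }
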