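"""Cost-effectiveness metrics: incremental analysis, ICER with dominance
sentinels, the dominance frontier, and the willingness-to-pay decision.

Conventions: incremental quantities are comparator minus reference, with the
cheaper strategy as reference. The ICER is ΔC/ΔE when ΔE ≠ 0; the degenerate
quadrants return sentinels — DOMINANT (cheaper and more effective),
DOMINATED (costlier and less effective), UNDEFINED (ΔE = 0). ΔC = 0 with
ΔE > 0 is a free gain, ICER 0.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import DomainError
from .parameters import EconomicConfig, ParameterBundle
from . import engine


class ICERSentinel(str, enum.Enum):
    DOMINANT = "dominant"      # ΔC < 0, ΔE > 0: adopt, no trade-off
    DOMINATED = "dominated"    # ΔC > 0, ΔE < 0: reject, no trade-off
    UNDEFINED = "undefined"    # ΔE = 0: ratio has no meaning


class Dominance(str, enum.Enum):
    DOMINATED = "dominated"
    EXTENDEDLY_DOMINATED = "extendedly_dominated"
    UNDOMINATED = "undominated"


def incremental(costs: Mapping[str, float], effects: Mapping[str, float],
                reference: str) -> tuple[float, float]:
    """(ΔC, ΔE) of the comparator relative to ``reference``; exact subtraction."""
    if reference not in costs or reference not in effects:
        raise DomainError(f"reference strategy {reference!r} not present")
    others = [k for k in costs if k != reference]
    if len(others) != 1:
        raise DomainError("incremental analysis requires exactly two strategies")
    cmp_ = others[0]
    return costs[cmp_] - costs[reference], effects[cmp_] - effects[reference]


def icer(delta_cost: float, delta_effect: float) -> float | ICERSentinel:
    """ΔC/ΔE, or a dominance sentinel in the degenerate quadrants."""
    if delta_effect == 0:
        return ICERSentinel.UNDEFINED
    if delta_effect > 0 and delta_cost < 0:
        return ICERSentinel.DOMINANT
    if delta_effect < 0 and delta_cost > 0:
        return ICERSentinel.DOMINATED
    return delta_cost / delta_effect


def average_ce_ratio(cost: float, effect: float) -> float:
    """Cost per QALY of a single strategy."""
    if effect <= 0:
        raise DomainError(f"effect must be > 0, got {effect}")
    return cost / effect


def decide(icer_value: float | ICERSentinel, wtp: float) -> bool:
    """True iff the comparator is cost-effective at the WTP threshold."""
    if wtp <= 0:
        raise DomainError(f"wtp must be > 0, got {wtp}")
    if icer_value is ICERSentinel.DOMINANT:
        return True
    if icer_value in (ICERSentinel.DOMINATED, ICERSentinel.UNDEFINED):
        return False
    return icer_value <= wtp


def dominance_frontier(strategies: Sequence[tuple[float, float]]) -> list[Dominance]:
    """Classify each (cost, effect) point.

    Strict dominance: some other point has cost ≤ and effect ≥, one strictly.
    Extended dominance: on the remaining points ordered by effect, a point
    whose incremental ICER from the previous frontier member exceeds the
    next member's is removed (a mix of its neighbours beats it). Exactly
    equal points are both kept (weak dominance not applied).
    """
    n = len(strategies)
    if n == 0:
        raise DomainError("at least one strategy required")
    cats = [Dominance.UNDOMINATED] * n
    for j in range(n):
        cj, ej = strategies[j]
        for k in range(n):
            if k == j:
                continue
            ck, ek = strategies[k]
            if ck <= cj and ek >= ej and (ck < cj or ek > ej):
                cats[j] = Dominance.DOMINATED
                break
    # extended dominance on the survivors, ordered by effect then cost
    frontier = [i for i in range(n) if cats[i] is Dominance.UNDOMINATED]
    frontier.sort(key=lambda i: (strategies[i][1], strategies[i][0]))
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for pos in range(1, len(frontier) - 1):
            i_prev, i_mid, i_next = frontier[pos - 1], frontier[pos], frontier[pos + 1]
            # exactly equal points are kept (weak dominance off): a point
            # duplicating a neighbour cannot be beaten by a blend of others
            if (strategies[i_mid] == strategies[i_prev]
                    or strategies[i_mid] == strategies[i_next]):
                continue

            def _icer(a, b):
                dc = strategies[b][0] - strategies[a][0]
                de = strategies[b][1] - strategies[a][1]
                return dc / de if de != 0 else float("inf")

            if _icer(i_prev, i_mid) > _icer(i_mid, i_next):
                cats[i_mid] = Dominance.EXTENDEDLY_DOMINATED
                frontier.pop(pos)
                changed = True
                break
    return cats


@dataclass
class CEAResult:
    """Cost-effectiveness comparison of the two arms at one discount rate."""

    costs: dict[str, float]
    effects: dict[str, float]
    reference: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | ICERSentinel
    average_ratios: dict[str, float]
    dominance: dict[str, Dominance]
    wtp_threshold: float
    cost_effective_at_wtp: bool
    discount_rate: float = field(default=0.05)

    def to_dataframe(self) -> pd.DataFrame:
        """Per-strategy table shaped like a standard CEA results table."""
        rows = []
        for name in (self.reference, self.comparator):
            is_ref = name == self.reference
            icer_val = (None if is_ref else
                        self.icer.value if isinstance(self.icer, ICERSentinel)
                        else self.icer)
            rows.append({
                "intervention": name,
                "cost": self.costs[name],
                "incremental_cost": None if is_ref else self.delta_cost,
                "effectiveness": self.effects[name],
                "incremental_effectiveness": None if is_ref else self.delta_effect,
                "icer": icer_val,
                "cost_per_effectiveness": self.average_ratios[name],
                "dominance": self.dominance[name].value,
            })
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        d = {
            "discount_rate": self.discount_rate,
            "reference": self.reference,
            "comparator": self.comparator,
            "costs": self.costs,
            "effects": self.effects,
            "delta_cost": self.delta_cost,
            "delta_effect": self.delta_effect,
            "icer": (self.icer.value if isinstance(self.icer, ICERSentinel)
                     else self.icer),
            "average_ratios": self.average_ratios,
            "dominance": {k: v.value for k, v in self.dominance.items()},
            "wtp_threshold": self.wtp_threshold,
            "cost_effective_at_wtp": self.cost_effective_at_wtp,
        }
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    def ce_plane_points(self) -> list[tuple[float, float]]:
        """(effect, cost) pairs for cost-effectiveness-plane plotting."""
        return [(self.effects[k], self.costs[k])
                for k in (self.reference, self.comparator)]


def compare(costs: Mapping[str, float], effects: Mapping[str, float],
            wtp: float, discount_rate: float = 0.05) -> CEAResult:
    """Build a :class:`CEAResult` from per-strategy totals.

    The reference is ``standard`` when present (the cheaper strategy in the
    base case; keeping it fixed makes sensitivity-run ICERs comparable, with
    a cost-saving comparator reported as DOMINANT). Otherwise the cheaper
    strategy is the reference.
    """
    if "standard" in costs:
        names = sorted(costs, key=lambda k: k != "standard")
    else:
        names = sorted(costs, key=lambda k: costs[k])
    reference, comparator = names[0], names[-1]
    dc, de = incremental(costs, effects, reference)
    icer_v = icer(dc, de)
    cats = dominance_frontier([(costs[n], effects[n]) for n in (reference, comparator)])
    return CEAResult(
        costs=dict(costs),
        effects=dict(effects),
        reference=reference,
        comparator=comparator,
        delta_cost=dc,
        delta_effect=de,
        icer=icer_v,
        average_ratios={n: average_ce_ratio(costs[n], effects[n]) for n in costs},
        dominance={n: c for n, c in zip((reference, comparator), cats)},
        wtp_threshold=wtp,
        cost_effective_at_wtp=decide(icer_v, wtp),
        discount_rate=discount_rate,
    )


def evaluate_bundle(bundle: ParameterBundle,
                    economics: EconomicConfig | None = None) -> CEAResult:
    """Full pipeline: run both arms on ``bundle`` and compare them."""
    eco = economics if economics is not None else bundle.economics
    std, inten = engine.run_strategy_pair(bundle, eco)
    costs = {"standard": std.total_cost_disc, "intensive": inten.total_cost_disc}
    effects = {"standard": std.total_qaly_disc, "intensive": inten.total_qaly_disc}
    return compare(costs, effects, eco.wtp_threshold, eco.discount_rate)
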