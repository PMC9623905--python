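"""Published cost-effectiveness results for the Korean hypertensive-CKD
cohort, used as comparison inputs.

These are the printed per-strategy totals of the original NHIS-based
evaluation at each discount rate (costs in USD, effectiveness in QALYs,
rounded as printed: one decimal for money, two for QALYs). The underlying
age-specific parameter estimates were never published, so these totals are
inputs for incremental arithmetic and cross-checks, not quantities this
package can re-derive from raw data.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ReportedArm:
    cost: float      # total discounted cost, USD
    effect: float    # total discounted effectiveness, QALY


#: Printed per-strategy totals by annual discount rate.
REPORTED_RESULTS: dict[float, dict[str, ReportedArm]] = {
    0.03: {
        "standard": ReportedArm(cost=195938.1, effect=15.39),
        "intensive": ReportedArm(cost=203133.1, effect=15.78),
    },
    0.05: {
        "standard": ReportedArm(cost=136298.1, effect=11.37),
        "intensive": ReportedArm(cost=140572.4, effect=11.60),
    },
    0.07: {
        "standard": ReportedArm(cost=101291.2, effect=8.90),
        "intensive": ReportedArm(cost=104023.4, effect=9.06),
    },
}

#: Printed ICERs (USD/QALY) by discount rate. These were computed from
#: unrounded internals, so they differ slightly from ratios of the printed
#: cells above (e.g. 7195.0 / 0.39 = 18448.7 vs the printed 18497.1).
REPORTED_ICER: dict[float, float] = {0.03: 18497.1, 0.05: 18125.7, 0.07: 17269.1}

#: Willingness-to-pay threshold, USD/QALY (2019 Korean GDP per capita).
REPORTED_WTP: float = 31362.80
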