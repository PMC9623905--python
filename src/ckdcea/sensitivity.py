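"""Deterministic sensitivity analyses: discount-rate scenarios and one-way
parameter variation with tornado ordering.

Parameters are addressed by dotted ids:

- ``hr.<target>``         — a hazard-ratio point value (e.g. ``hr.injurious_fall``)
- ``utility.<class>``     — a utility class weight (hypertension/mi/stroke/hf/sae)
- ``cost_multiplier.intensive`` — the intensive healthy-state cost multiplier
- ``economics.discount_rate``   — the annual discount rate

The default tornado varies each of the published hazard ratios across its
95% confidence interval, all else at base case, and sorts bars by descending
ICER swing. A bar endpoint whose ICER is a dominance sentinel is plotted at
0 with the sentinel recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .cea import CEAResult, ICERSentinel, evaluate_bundle
from .errors import DomainError, UnknownReferenceError
from .parameters import ParameterBundle, UTILITY_DEFAULTS, SAE_NAMES, HEALTHY


def set_parameter(bundle: ParameterBundle, parameter: str, value: float) -> None:
    """Set one addressable parameter in place; unknown ids raise."""
    parts = parameter.split(".")
    if len(parts) != 2:
        raise UnknownReferenceError(parameter)
    kind, name = parts
    if kind == "hr":
        if name not in bundle.hazard_ratios:
            raise UnknownReferenceError(parameter)
        hr = bundle.hazard_ratios[name]
        hr.point = float(value)
        hr.ci_low = min(hr.ci_low, hr.point)
        hr.ci_high = max(hr.ci_high, hr.point)
    elif kind == "utility":
        if name not in UTILITY_DEFAULTS:
            raise UnknownReferenceError(parameter)
        w = bundle.utilities.weights
        if name == "hypertension":
            w[HEALTHY] = float(value)
        elif name == "sae":
            for s in SAE_NAMES:
                w[s] = float(value)
        else:
            w[name] = float(value)
    elif kind == "cost_multiplier":
        if name not in bundle.strategies:
            raise UnknownReferenceError(parameter)
        bundle.strategies[name].healthy_cost_multiplier = float(value)
    elif kind == "economics":
        if name != "discount_rate":
            raise UnknownReferenceError(parameter)
        bundle.economics.discount_rate = float(value)
    else:
        raise UnknownReferenceError(parameter)


def discount_scenarios(bundle: ParameterBundle,
                       rates: Sequence[float]) -> dict[float, CEAResult]:
    """Re-run the full pipeline at each discount rate, all else fixed."""
    results: dict[float, CEAResult] = {}
    for rate in rates:
        if not (0.0 <= rate < 1.0):
            raise DomainError(f"discount rate must lie in [0, 1), got {rate}")
        b = bundle.copy()
        b.economics.discount_rate = float(rate)
        results[float(rate)] = evaluate_bundle(b)
    return results


def scenarios_to_dataframe(results: dict[float, CEAResult]) -> pd.DataFrame:
    """Scenario table: one block of per-strategy rows per discount rate."""
    frames = []
    for rate in sorted(results):
        df = results[rate].to_dataframe()
        df.insert(0, "discount_rate", rate)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@dataclass
class TornadoBar:
    """One-way variation of a parameter over [low, high]."""

    parameter: str
    low: float
    high: float
    icer_low: float          # plotted value (0 when a sentinel was hit)
    icer_high: float
    swing: float
    low_sentinel: str | None = None
    high_sentinel: str | None = None


def _plot_value(icer_v) -> tuple[float, str | None]:
    if isinstance(icer_v, ICERSentinel):
        return 0.0, icer_v.value
    return float(icer_v), None


def one_way(bundle: ParameterBundle, parameter: str, low: float,
            high: float) -> TornadoBar:
    """Re-run the pipeline with ``parameter`` at ``low`` then ``high``."""
    if low > high:
        raise DomainError(f"low {low} exceeds high {high} for {parameter!r}")
    icers = []
    for value in (low, high):
        b = bundle.copy()
        set_parameter(b, parameter, value)
        icers.append(evaluate_bundle(b).icer)
    (v_low, s_low), (v_high, s_high) = _plot_value(icers[0]), _plot_value(icers[1])
    return TornadoBar(parameter=parameter, low=float(low), high=float(high),
                      icer_low=v_low, icer_high=v_high,
                      swing=abs(v_high - v_low),
                      low_sentinel=s_low, high_sentinel=s_high)


def default_tornado_parameters(bundle: ParameterBundle) -> list[tuple[str, float, float]]:
    """Each published hazard ratio over its 95% CI."""
    return [(f"hr.{t}", hr.ci_low, hr.ci_high)
            for t, hr in bundle.hazard_ratios.items()]


def tornado(bundle: ParameterBundle,
            parameters: Sequence[tuple[str, float, float]] | None = None
            ) -> list[TornadoBar]:
    """One-way bars for every parameter, sorted by descending swing."""
    if parameters is None:
        parameters = default_tornado_parameters(bundle)
    if not parameters:
        raise DomainError("tornado requires at least one parameter")
    bars = [one_way(bundle, pid, lo, hi) for pid, lo, hi in parameters]
    bars.sort(key=lambda b: (-b.swing, b.parameter))
    return bars


def tornado_to_dataframe(bars: Sequence[TornadoBar]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": b.parameter,
        "low": b.low,
        "high": b.high,
        "icer_low": b.icer_low,
        "icer_high": b.icer_high,
        "swing": b.swing,
        "low_sentinel": b.low_sentinel or "",
        "high_sentinel": b.high_sentinel or "",
    } for b in bars])
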