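"""Synthetic parameter bundles and cohorts.

The original incidence, mortality and cost curves were estimated from
national claims data and published only as (low, high) ranges over the
cohort's age span, so no age-specific values can be recovered. This module
generates complete, internally consistent stand-ins inside those ranges:

- ``default``      — the pinned deterministic bundle (identical to the
  bundled default config): incidence/mortality linear between the range
  endpoints over ages 50..100, costs at range midpoints, hazard ratios and
  utilities at their published point values. Headline runs use this bundle.
- ``midpoint``     — every curve constant at its range midpoint.
- ``range_sample`` — both endpoints of each curve drawn uniformly within its
  printed range (seeded), linear in between; optional multiplicative jitter,
  clipped back into the printed range and the probability simplex.

Cohorts are starting ages >= 50 drawn from a configurable distribution
(uniform over 50..79 by default; the source population is only described as
aged 50 or older).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError
from .parameters import (
    AgeCurve,
    CurveRole,
    ParameterBundle,
    default_bundle,
)

MODES = ("default", "midpoint", "range_sample")


def _uniform_age_weights(lo: int = 50, hi: int = 79) -> dict[int, float]:
    return {a: 1.0 / (hi - lo + 1) for a in range(lo, hi + 1)}


@dataclass
class SynthSpec:
    """Recipe for one synthetic parameter set / cohort."""

    seed: int = 0
    mode: str = "default"
    noise_sd_frac: float = 0.0
    start_age_distribution: dict[int, float] = field(
        default_factory=_uniform_age_weights)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise DomainError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.noise_sd_frac < 0:
            raise DomainError("noise_sd_frac must be >= 0")
        if not self.start_age_distribution:
            raise DomainError("start_age_distribution must be non-empty")
        ages = np.array(sorted(self.start_age_distribution))
        if ages.min() < 50:
            raise DomainError("starting ages must be >= 50")
        w = np.array([self.start_age_distribution[a] for a in ages])
        if w.min() < 0 or w.sum() <= 0:
            raise DomainError("start-age weights must be non-negative, summing > 0")


def _clip_curve(values: np.ndarray, role: CurveRole,
                printed_range: tuple[float, float] | None) -> np.ndarray:
    if printed_range is not None:
        values = np.clip(values, printed_range[0], printed_range[1])
    if role in (CurveRole.INCIDENCE, CurveRole.MORTALITY):
        values = np.clip(values, 0.0, 1.0)
    else:
        values = np.clip(values, 0.0, None)
    return values


def generate_param_set(spec: SynthSpec) -> ParameterBundle:
    """Generate a fully validated parameter bundle per ``spec``.

    ``default`` mode involves no randomness; ``range_sample`` draws each
    curve's endpoints from a generator seeded once with ``spec.seed``, so
    equal seeds give identical bundles.
    """
    spec.validate()
    bundle = default_bundle()
    if spec.mode == "default" and spec.noise_sd_frac == 0.0:
        return bundle
    rng = np.random.default_rng(spec.seed)
    for name, curve in bundle.age_curves.items():
        lo, hi = curve.printed_range
        n = len(curve.values)
        if spec.mode == "midpoint":
            values = np.full(n, (lo + hi) / 2.0)
        elif spec.mode == "range_sample":
            e0, e1 = rng.uniform(lo, hi, size=2)
            values = np.linspace(e0, e1, n)
        else:
            values = curve.values.astype(float).copy()
        if spec.noise_sd_frac > 0:
            values = values * (1.0 + spec.noise_sd_frac * rng.standard_normal(n))
        curve.values = _clip_curve(values, curve.role, curve.printed_range)
    bundle.validate()
    return bundle


def generate_cohort(spec: SynthSpec, n: int) -> np.ndarray:
    """Draw ``n`` integer starting ages from the spec's age distribution."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ages = np.array(sorted(spec.start_age_distribution))
    w = np.array([spec.start_age_distribution[a] for a in ages], dtype=float)
    w = w / w.sum()
    return rng.choice(ages, size=n, p=w)
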