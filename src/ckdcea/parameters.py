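"""Model parameters: domain types, published constants, config I/O, validation.

The model describes hypertensive chronic-kidney-disease (CKD) patients aged 50+
managed under one of two blood-pressure strategies (standard: 140/90 mmHg
target; intensive: 120/80 mmHg). Patients move yearly between a healthy
hypertensive-CKD state, six acute serious-adverse-event (SAE) states caused by
antihypertensive drugs, three chronic cardiovascular-disease (CVD) states, and
death. Annual incidence, mortality and per-state costs are age dependent and
published only as ranges over the cohort's age span; the intensive arm is
characterised by hazard ratios on each event plus a 1.2x outpatient cost
multiplier on the healthy state.

All monetary amounts are USD per person per year (fixed 1,180 KRW/USD);
utilities are QALY weights per year in [0, 1]; probabilities are annual.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    ConfigError,
    DomainError,
    MissingParameterError,
    RangeError,
    UnknownReferenceError,
)

# --------------------------------------------------------------------------
# State space
# --------------------------------------------------------------------------

SAE_NAMES: tuple[str, ...] = (
    "hypotension",
    "syncope",
    "bradycardia",
    "electrolyte_abnormality",
    "injurious_fall",
    "acute_renal_failure",
)
CVD_NAMES: tuple[str, ...] = ("mi", "stroke", "hf")
#: Events that can occur from the healthy state, each with an incidence curve.
EVENT_NAMES: tuple[str, ...] = SAE_NAMES + CVD_NAMES

HEALTHY = "healthy"
DEATH = "death"
#: Canonical state ordering used by every transition matrix and trace.
STATE_ORDER: tuple[str, ...] = (HEALTHY,) + SAE_NAMES + CVD_NAMES + (DEATH,)


class StateKind(str, enum.Enum):
    HEALTHY = "healthy"
    SAE = "sae"
    CVD = "cvd"
    DEATH = "death"


class DeathAttribution(str, enum.Enum):
    CVD = "cvd"
    NON_CVD = "non_cvd"
    NONE = "none"


@dataclass(frozen=True)
class HealthState:
    """One state of the Markov model.

    ``death_attribution`` records which mortality hazard ratio governs deaths
    occurring *from* this state in the intensive arm: deaths from CVD states
    use the CVD-death hazard ratio, all others the non-CVD-death one.
    """

    id: str
    kind: StateKind
    sae_name: str | None = None
    cvd_name: str | None = None
    death_attribution: DeathAttribution = DeathAttribution.NONE


def default_states() -> list[HealthState]:
    states = [HealthState(HEALTHY, StateKind.HEALTHY,
                          death_attribution=DeathAttribution.NON_CVD)]
    for name in SAE_NAMES:
        states.append(HealthState(name, StateKind.SAE, sae_name=name,
                                  death_attribution=DeathAttribution.NON_CVD))
    for name in CVD_NAMES:
        states.append(HealthState(name, StateKind.CVD, cvd_name=name,
                                  death_attribution=DeathAttribution.CVD))
    states.append(HealthState(DEATH, StateKind.DEATH))
    return states


def state_index(state_id: str) -> int:
    try:
        return STATE_ORDER.index(state_id)
    except ValueError:
        raise UnknownReferenceError(state_id) from None


# --------------------------------------------------------------------------
# Published input constants (annual probabilities, USD, QALY weights)
# --------------------------------------------------------------------------

#: Age-dependent annual incidence among hypertensive CKD patients, printed
#: as (low, high) over the modelled age span.
INCIDENCE_RANGES: dict[str, tuple[float, float]] = {
    "mi": (0.0, 0.0082),
    "stroke": (0.0247, 0.0604),
    "hf": (0.0247, 0.1275),
    "hypotension": (0.0, 0.0083),
    "syncope": (0.0, 0.0201),
    "bradycardia": (0.0, 0.0132),
    "electrolyte_abnormality": (0.0201, 0.0331),
    "injurious_fall": (0.3423, 0.3786),
    "acute_renal_failure": (0.0041, 0.0470),
}

#: Age-dependent annual mortality: hypertension background mortality applies
#: in the healthy state, the others within the corresponding event state.
#: MI mortality is printed as 0% and is taken literally.
MORTALITY_RANGES: dict[str, tuple[float, float]] = {
    "hypertension": (0.0004, 0.0053),
    "mi": (0.0, 0.0),
    "stroke": (0.0, 0.0067),
    "hf": (0.0, 0.0201),
    "hypotension": (0.0, 0.0041),
    "syncope": (0.0, 0.0028),
    "bradycardia": (0.0, 0.0),
    "electrolyte_abnormality": (0.0, 0.0026),
    "injurious_fall": (0.0041, 0.0134),
    "acute_renal_failure": (0.0, 0.0201),
}

#: Per-person annual direct medical cost, USD, printed as (low, high).
COST_RANGES: dict[str, tuple[float, float]] = {
    "hypertension": (386.4, 1943.3),
    "mi": (159.8, 26696.9),
    "stroke": (2406.1, 14109.8),
    "hf": (4508.8, 6371.5),
    "hypotension": (67.0, 7930.4),
    "syncope": (494.6, 2882.2),
    "bradycardia": (365.0, 3643.9),
    "electrolyte_abnormality": (643.6, 5511.5),
    "injurious_fall": (4157.2, 14087.9),
    "acute_renal_failure": (5418.7, 27676.9),
}

#: Intensive-vs-standard hazard ratios with 95% CIs. ``disease_events`` is the
#: published aggregate over all disease events; the transition model applies
#: the per-event ratios, so the aggregate is carried for completeness only.
HAZARD_RATIO_TABLE: dict[str, tuple[float, float, float]] = {
    "disease_events": (0.94, 0.62, 1.44),
    "mi": (1.35, 0.60, 3.08),
    "stroke": (0.99, 0.57, 1.70),
    "hf": (0.72, 0.47, 1.10),
    "hypotension": (1.34, 0.88, 2.04),
    "syncope": (1.28, 0.86, 1.92),
    "bradycardia": (0.92, 0.59, 1.44),
    "electrolyte_abnormality": (1.35, 0.94, 1.94),
    "injurious_fall": (0.90, 0.71, 1.15),
    "acute_renal_failure": (1.46, 1.10, 1.95),
    "cvd_death": (0.57, 0.31, 1.02),
    "non_cvd_death": (0.72, 0.53, 0.99),
}

#: QALY weights per year in each state class.
UTILITY_DEFAULTS: dict[str, float] = {
    "hypertension": 1.00,
    "stroke": 0.65,
    "mi": 0.70,
    "hf": 0.64,
    "sae": 0.60,
}

KRW_PER_USD_DEFAULT = 1180.0
DISCOUNT_RATE_DEFAULT = 0.05
#: 2019 Korean GDP per capita, the willingness-to-pay threshold (USD/QALY).
WTP_THRESHOLD_DEFAULT = 31362.80
COHORT_SIZE_DEFAULT = 72429
START_AGE_DEFAULT = 50
MAX_AGE_DEFAULT = 100


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

class CurveRole(str, enum.Enum):
    INCIDENCE = "incidence"
    MORTALITY = "mortality"
    COST = "cost"


@dataclass
class AgeCurve:
    """An age-indexed annual parameter on integer ages ``age_min..age_max``.

    ``values[i]`` is the value at age ``age_min + i``. When the source prints
    only a (low, high) range, :meth:`from_range` expands it: ``linear``
    interpolates low at ``age_min`` to high at ``age_max`` (event risks in
    this population rise with age), ``midpoint`` is constant at the range
    mean, ``constant_low``/``constant_high`` pin an endpoint.
    """

    name: str
    role: CurveRole
    age_min: int
    age_max: int
    values: np.ndarray
    printed_range: tuple[float, float] | None = None

    @classmethod
    def from_range(cls, name: str, role: CurveRole | str, age_min: int,
                   age_max: int, low: float, high: float,
                   form: str = "linear") -> "AgeCurve":
        n = age_max - age_min + 1
        if form == "linear":
            values = np.linspace(low, high, n)
        elif form == "midpoint":
            values = np.full(n, (low + high) / 2.0)
        elif form == "constant_low":
            values = np.full(n, low)
        elif form == "constant_high":
            values = np.full(n, high)
        else:
            raise ConfigError(f"unknown age-curve form {form!r} for {name!r}")
        return cls(name, CurveRole(role), age_min, age_max, values, (low, high))

    def validate(self) -> None:
        n = self.age_max - self.age_min + 1
        if self.age_min < 0 or self.age_max < self.age_min:
            raise RangeError(f"{self.name}.age_max", self.age_max,
                             "requires 0 <= age_min <= age_max")
        if len(self.values) != n:
            raise ConfigError(
                f"curve {self.name!r}: {len(self.values)} values for "
                f"{n} ages {self.age_min}..{self.age_max}")
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise RangeError(self.name, "non-finite", "values must be finite")
        if self.role in (CurveRole.INCIDENCE, CurveRole.MORTALITY):
            if v.min() < 0.0 or v.max() > 1.0:
                raise RangeError(self.name, float(v.min() if v.min() < 0 else v.max()),
                                 "annual probabilities must lie in [0, 1]")
        else:
            if v.min() < 0.0:
                raise RangeError(self.name, float(v.min()), "costs must be >= 0")
        if self.printed_range is not None:
            lo, hi = self.printed_range
            tol = 1e-9 * max(1.0, abs(hi))
            if v.min() < lo - tol or v.max() > hi + tol:
                raise RangeError(self.name, float(v.min() if v.min() < lo else v.max()),
                                 f"values must stay within printed range [{lo}, {hi}]")

    def value_at(self, age: float) -> float:
        """Curve value at ``age``; non-integer ages interpolate linearly."""
        if age < self.age_min or age > self.age_max:
            raise DomainError(
                f"age {age} outside curve {self.name!r} domain "
                f"[{self.age_min}, {self.age_max}]")
        ages = np.arange(self.age_min, self.age_max + 1)
        return float(np.interp(age, ages, self.values))

    def equivalent(self, other: "AgeCurve") -> bool:
        return (self.name == other.name and self.role == other.role
                and self.age_min == other.age_min and self.age_max == other.age_max
                and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
                and self.printed_range == other.printed_range)


def interpolate_age_param(curve: AgeCurve, age: float) -> float:
    """Annual value of ``curve`` at ``age`` (see :meth:`AgeCurve.value_at`)."""
    return curve.value_at(age)


@dataclass
class HazardRatio:
    """Multiplicative effect of intensive control on one event rate."""

    target: str
    point: float
    ci_low: float
    ci_high: float

    def validate(self) -> None:
        if not (0.0 < self.ci_low <= self.point <= self.ci_high):
            raise RangeError(f"hazard_ratio.{self.target}", self.point,
                             "requires 0 < ci_low <= point <= ci_high")


@dataclass
class UtilityTable:
    """QALY weight per year for every state; death is exactly 0."""

    weights: dict[str, float]

    @classmethod
    def from_class_weights(cls, class_weights: Mapping[str, float]) -> "UtilityTable":
        for key in UTILITY_DEFAULTS:
            if key not in class_weights:
                raise MissingParameterError(f"utilities.{key}")
        w: dict[str, float] = {HEALTHY: float(class_weights["hypertension"])}
        for name in SAE_NAMES:
            w[name] = float(class_weights["sae"])
        for name in CVD_NAMES:
            w[name] = float(class_weights[name])
        w[DEATH] = 0.0
        return cls(w)

    def validate(self) -> None:
        for sid in STATE_ORDER:
            if sid not in self.weights:
                raise MissingParameterError(f"utilities.{sid}")
            v = self.weights[sid]
            if not (0.0 <= v <= 1.0):
                raise RangeError(f"utilities.{sid}", v, "utility weights lie in [0, 1]")
        if self.weights[DEATH] != 0.0:
            raise RangeError("utilities.death", self.weights[DEATH],
                             "death utility must be exactly 0")

    def vector(self) -> np.ndarray:
        return np.array([self.weights[s] for s in STATE_ORDER])

    def class_weights(self) -> dict[str, float]:
        return {
            "hypertension": self.weights[HEALTHY],
            "mi": self.weights["mi"],
            "stroke": self.weights["stroke"],
            "hf": self.weights["hf"],
            "sae": self.weights[SAE_NAMES[0]],
        }


class HRApplication(str, enum.Enum):
    RATE_TRANSFORM = "rate_transform"
    PROBABILITY_MULTIPLY = "probability_multiply"


@dataclass
class StrategySpec:
    """One treatment arm.

    The standard arm carries no hazard ratios (all effectively 1) and a unit
    cost multiplier; the intensive arm applies the published hazard ratios and
    multiplies the healthy-state annual cost by ``healthy_cost_multiplier``
    (default 1.2, the extra outpatient burden of tighter BP control).
    """

    name: str
    hazard_ratios: dict[str, HazardRatio] = field(default_factory=dict)
    healthy_cost_multiplier: float = 1.0
    hr_application: HRApplication = HRApplication.RATE_TRANSFORM

    def hr_point(self, target: str) -> float:
        hr = self.hazard_ratios.get(target)
        return 1.0 if hr is None else hr.point

    def validate(self) -> None:
        if self.name == "standard":
            if self.healthy_cost_multiplier != 1.0:
                raise RangeError("strategies.standard.healthy_cost_multiplier",
                                 self.healthy_cost_multiplier, "must equal 1 for standard")
            if self.hazard_ratios:
                raise ConfigError("standard strategy must not carry hazard ratios")
        elif self.healthy_cost_multiplier < 1.0:
            raise RangeError(f"strategies.{self.name}.healthy_cost_multiplier",
                             self.healthy_cost_multiplier, "must be >= 1")
        for hr in self.hazard_ratios.values():
            hr.validate()


@dataclass
class EconomicConfig:
    """Discounting, threshold, currency and cohort settings."""

    discount_rate: float = DISCOUNT_RATE_DEFAULT
    wtp_threshold: float = WTP_THRESHOLD_DEFAULT
    krw_per_usd: float = KRW_PER_USD_DEFAULT
    cycle_length: float = 1.0
    start_age: int = START_AGE_DEFAULT
    max_age: int = MAX_AGE_DEFAULT
    cohort_size: int = COHORT_SIZE_DEFAULT
    half_cycle_correction: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.discount_rate < 1.0):
            raise RangeError("economics.discount_rate", self.discount_rate,
                             "requires 0 <= rate < 1")
        if self.cycle_length != 1.0:
            raise RangeError("economics.cycle_length", self.cycle_length,
                             "the default model uses 1-year cycles")
        if self.wtp_threshold <= 0:
            raise RangeError("economics.wtp_threshold", self.wtp_threshold, "must be > 0")
        if self.krw_per_usd <= 0:
            raise RangeError("economics.krw_per_usd", self.krw_per_usd, "must be > 0")
        if self.start_age < 50:
            raise RangeError("economics.start_age", self.start_age,
                             "modelled population is aged 50 or older")
        if self.max_age <= self.start_age:
            raise RangeError("economics.max_age", self.max_age, "must exceed start_age")
        if self.cohort_size < 1:
            raise RangeError("economics.cohort_size", self.cohort_size, "must be >= 1")


class CompetingRiskMethod(str, enum.Enum):
    RATE_BASED = "rate_based"
    DIRECT_SUM = "direct_sum"


@dataclass
class ParameterBundle:
    """Fully validated parameter set: states, curves, utilities, hazard
    ratios, strategies and economic settings."""

    states: list[HealthState]
    age_curves: dict[str, AgeCurve]
    utilities: UtilityTable
    hazard_ratios: dict[str, HazardRatio]
    strategies: dict[str, StrategySpec]
    economics: EconomicConfig
    competing_risk_method: CompetingRiskMethod = CompetingRiskMethod.RATE_BASED
    sae_persistent: bool = False

    def validate(self) -> None:
        ids = [s.id for s in self.states]
        if ids != list(STATE_ORDER):
            raise ConfigError("state space must match the default model topology")
        for curve in self.age_curves.values():
            curve.validate()
        for name in EVENT_NAMES:
            if f"incidence_{name}" not in self.age_curves:
                raise MissingParameterError(f"age_curves.incidence.{name}")
        for name in ("hypertension",) + EVENT_NAMES:
            if f"mortality_{name}" not in self.age_curves:
                raise MissingParameterError(f"age_curves.mortality.{name}")
            if f"cost_{name}" not in self.age_curves:
                raise MissingParameterError(f"age_curves.costs.{name}")
        self.utilities.validate()
        for hr in self.hazard_ratios.values():
            hr.validate()
        for name in ("standard", "intensive"):
            if name not in self.strategies:
                raise MissingParameterError(f"strategies.{name}")
        for strat in self.strategies.values():
            strat.validate()
            for target in strat.hazard_ratios:
                if target not in self.hazard_ratios:
                    raise UnknownReferenceError(f"hazard_ratio.{target}")
        self.economics.validate()

    def curve(self, name: str) -> AgeCurve:
        try:
            return self.age_curves[name]
        except KeyError:
            raise UnknownReferenceError(name) from None

    def copy(self) -> "ParameterBundle":
        return copy.deepcopy(self)

    def equivalent(self, other: "ParameterBundle") -> bool:
        if set(self.age_curves) != set(other.age_curves):
            return False
        if not all(self.age_curves[k].equivalent(other.age_curves[k])
                   for k in self.age_curves):
            return False
        return (self.utilities.weights == other.utilities.weights
                and self.hazard_ratios == other.hazard_ratios
                and {k: (v.healthy_cost_multiplier, v.hr_application,
                         sorted(v.hazard_ratios))
                     for k, v in self.strategies.items()}
                == {k: (v.healthy_cost_multiplier, v.hr_application,
                        sorted(v.hazard_ratios))
                    for k, v in other.strategies.items()}
                and self.economics == other.economics
                and self.competing_risk_method == other.competing_risk_method
                and self.sae_persistent == other.sae_persistent)


# --------------------------------------------------------------------------
# Currency
# --------------------------------------------------------------------------

def convert_krw_to_usd(amount_krw: float, krw_per_usd: float = KRW_PER_USD_DEFAULT) -> float:
    """Convert Korean won to US dollars at the fixed study exchange rate."""
    if amount_krw < 0:
        raise DomainError(f"amount_krw must be >= 0, got {amount_krw}")
    if krw_per_usd <= 0:
        raise DomainError(f"krw_per_usd must be > 0, got {krw_per_usd}")
    return amount_krw / krw_per_usd


# --------------------------------------------------------------------------
# Config I/O (YAML dialect)
# --------------------------------------------------------------------------

_ROLE_SECTION = {"incidence": CurveRole.INCIDENCE,
                 "mortality": CurveRole.MORTALITY,
                 "costs": CurveRole.COST}
_SECTION_PREFIX = {"incidence": "incidence_", "mortality": "mortality_",
                   "costs": "cost_"}


def _load_curve(section: str, name: str, node: Mapping, age_min: int,
                age_max: int) -> AgeCurve:
    role = _ROLE_SECTION[section]
    cname = _SECTION_PREFIX[section] + name
    if "values" in node:
        values = np.asarray(node["values"], dtype=float)
        rng = tuple(node["range"]) if "range" in node else None
        curve = AgeCurve(cname, role, age_min, age_max, values, rng)
    elif "range" in node:
        low, high = node["range"]
        form = node.get("form", "linear")
        curve = AgeCurve.from_range(cname, role, age_min, age_max, low, high, form)
    else:
        raise MissingParameterError(f"age_curves.{section}.{name}.range")
    curve.validate()
    return curve


def load_config(path) -> ParameterBundle:
    """Load and validate a model configuration file.

    Returns the full parameter bundle (states, age curves, utilities,
    strategies, economics). Any invariant violation raises a
    :class:`~ckdcea.errors.ConfigError` naming the offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return bundle_from_dict(raw)


def bundle_from_dict(raw: Mapping) -> ParameterBundle:
    eco_raw = dict(raw.get("economics", {}))
    known = {f for f in EconomicConfig.__dataclass_fields__}
    unknown = set(eco_raw) - known
    if unknown:
        raise UnknownReferenceError(f"economics.{sorted(unknown)[0]}")
    economics = EconomicConfig(**eco_raw)

    model_raw = dict(raw.get("model", {}))
    crm = CompetingRiskMethod(model_raw.get("competing_risk_method", "rate_based"))
    sae_persistent = bool(model_raw.get("sae_persistent", False))

    age_min, age_max = economics.start_age, economics.max_age
    curves_raw = raw.get("age_curves")
    if curves_raw is None:
        raise MissingParameterError("age_curves")
    age_curves: dict[str, AgeCurve] = {}
    for section in ("incidence", "mortality", "costs"):
        sec = curves_raw.get(section)
        if sec is None:
            raise MissingParameterError(f"age_curves.{section}")
        for name, node in sec.items():
            curve = _load_curve(section, name, node, age_min, age_max)
            age_curves[curve.name] = curve

    util_raw = raw.get("utilities")
    if util_raw is None:
        raise MissingParameterError("utilities")
    utilities = UtilityTable.from_class_weights(util_raw)

    hrs_raw = raw.get("hazard_ratios", {})
    hazard_ratios = {}
    for target, node in hrs_raw.items():
        lo, hi = node.get("ci", (node["point"], node["point"]))
        hazard_ratios[target] = HazardRatio(target, float(node["point"]),
                                            float(lo), float(hi))

    strat_raw = raw.get("strategies", {
        "standard": {}, "intensive": {"healthy_cost_multiplier": 1.2,
                                      "apply_hazard_ratios": True}})
    strategies = {}
    for name, node in strat_raw.items():
        node = dict(node or {})
        apply_hrs = node.get("apply_hazard_ratios", name != "standard")
        strategies[name] = StrategySpec(
            name=name,
            hazard_ratios=hazard_ratios if apply_hrs else {},
            healthy_cost_multiplier=float(node.get(
                "healthy_cost_multiplier", 1.2 if name == "intensive" else 1.0)),
            hr_application=HRApplication(node.get("hr_application", "rate_transform")),
        )

    bundle = ParameterBundle(
        states=default_states(),
        age_curves=age_curves,
        utilities=utilities,
        hazard_ratios=hazard_ratios,
        strategies=strategies,
        economics=economics,
        competing_risk_method=crm,
        sae_persistent=sae_persistent,
    )
    bundle.validate()
    return bundle


def bundle_to_dict(bundle: ParameterBundle) -> dict:
    """Serialise a bundle to the config dialect (explicit per-age values)."""
    curves: dict[str, dict] = {"incidence": {}, "mortality": {}, "costs": {}}
    for section, prefix in _SECTION_PREFIX.items():
        for cname, curve in bundle.age_curves.items():
            if not cname.startswith(prefix):
                continue
            if _ROLE_SECTION[section] is not curve.role:
                continue
            node: dict = {"values": [float(v) for v in curve.values]}
            if curve.printed_range is not None:
                node["range"] = [float(curve.printed_range[0]),
                                 float(curve.printed_range[1])]
            curves[section][cname[len(prefix):]] = node
    eco = bundle.economics
    return {
        "model": {
            "competing_risk_method": bundle.competing_risk_method.value,
            "sae_persistent": bundle.sae_persistent,
        },
        "economics": {
            "discount_rate": eco.discount_rate,
            "wtp_threshold": eco.wtp_threshold,
            "krw_per_usd": eco.krw_per_usd,
            "cycle_length": eco.cycle_length,
            "start_age": eco.start_age,
            "max_age": eco.max_age,
            "cohort_size": eco.cohort_size,
            "half_cycle_correction": eco.half_cycle_correction,
        },
        "age_curves": curves,
        "utilities": bundle.utilities.class_weights(),
        "hazard_ratios": {
            t: {"point": hr.point, "ci": [hr.ci_low, hr.ci_high]}
            for t, hr in bundle.hazard_ratios.items()
        },
        "strategies": {
            name: {
                "healthy_cost_multiplier": s.healthy_cost_multiplier,
                "apply_hazard_ratios": bool(s.hazard_ratios),
                "hr_application": s.hr_application.value,
            }
            for name, s in bundle.strategies.items()
        },
    }


def write_config(bundle: ParameterBundle, path) -> None:
    """Write a bundle back to a config file; ``load_config`` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(bundle_to_dict(bundle), fh, sort_keys=False)


def default_config_path():
    """Path to the bundled default configuration."""
    return resources.files("ckdcea.data") / "default.yaml"


def default_bundle() -> ParameterBundle:
    """The pinned default parameter bundle used for headline runs.

    Incidence and mortality interpolate linearly across ages 50..100 between
    the published range endpoints; costs are constant at range midpoints;
    utilities and hazard ratios are the published point values.
    """
    with resources.as_file(default_config_path()) as p:
        return load_config(p)
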