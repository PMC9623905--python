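import numpy as np
import pytest

from ckdcea.parameters import default_bundle


@pytest.fixture(scope="session")
def base_bundle_readonly():
    return default_bundle()


@pytest.fixture()
def bundle(base_bundle_readonly):
    """A fresh copy of the pinned default bundle, safe to mutate."""
    return base_bundle_readonly.copy()


def make_toy_bundle(incidence=None, mortality=None, costs=None,
                    utilities=None, max_age=100, discount_rate=0.0,
                    intensive_multiplier=1.2):
    """Default bundle with every curve zeroed, then constant overrides.

    ``incidence``/``mortality``/``costs`` map event/state names to constant
    annual values; printed ranges are dropped so arbitrary toy values pass
    validation.
    """
    b = default_bundle()
    b.economics.max_age = max_age
    b.economics.discount_rate = discount_rate
    b.strategies["intensive"].healthy_cost_multiplier = intensive_multiplier
    n = max_age - b.economics.start_age + 1
    for curve in b.age_curves.values():
        curve.age_max = max_age
        curve.values = np.zeros(n)
        curve.printed_range = None
    for section, mapping in (("incidence", incidence or {}),
                             ("mortality", mortality or {}),
                             ("cost", costs or {})):
        for name, value in mapping.items():
            curve = b.age_curves[f"{section}_{name}"]
            curve.values = np.full(n, float(value))
    if utilities:
        for state, w in utilities.items():
            b.utilities.weights[state] = w
    b.validate()
    return b


@pytest.fixture()
def toy_factory():
    return make_toy_bundle
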