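"""Transition-matrix construction, cohort traces, and the microsimulation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckdcea import errors
from ckdcea.engine import (
    N_STATES,
    adjust_probability,
    build_transition_matrix,
    microsim_oracle,
    run_cohort,
    run_strategy_pair,
    state_cost_vector,
)
from ckdcea.parameters import (
    CompetingRiskMethod,
    STATE_ORDER,
    state_index,
)
from ckdcea.synthetic import SynthSpec, generate_param_set

HEALTHY_I = state_index("healthy")
DEATH_I = state_index("death")


class TestAdjustProbability:
    @pytest.mark.parametrize("method", ["rate_transform", "probability_multiply"])
    def test_identity_at_unit_hazard_ratio(self, method):
        assert adjust_probability(0.1, 1.0, method) == pytest.approx(0.1)

    def test_zero_risk_stays_zero(self):
        assert adjust_probability(0.0, 1.46) == 0.0

    def test_rate_transform_closed_form(self):
        # 1 - (1 - 0.1)^2 = 1 - 0.81
        assert adjust_probability(0.1, 2.0, "rate_transform") == pytest.approx(0.19)

    def test_probability_multiply_saturates_at_one(self):
        assert adjust_probability(0.8, 2.0, "probability_multiply") == 1.0

    @pytest.mark.parametrize("p,hr", [(-0.1, 1.0), (1.1, 1.0), (0.5, 0.0),
                                      (0.5, -2.0)])
    def test_domain_errors(self, p, hr):
        with pytest.raises(errors.DomainError):
            adjust_probability(p, hr)

    @given(p=st.floats(0.0, 0.99), hr1=st.floats(0.01, 5.0),
           hr2=st.floats(0.01, 5.0))
    @settings(max_examples=100, derandomize=True)
    def test_increasing_in_hazard_ratio(self, p, hr1, hr2):
        lo, hi = sorted((hr1, hr2))
        assert (adjust_probability(p, lo, "rate_transform")
                <= adjust_probability(p, hi, "rate_transform") + 1e-15)

    @given(hr=st.floats(0.1, 3.0))
    @settings(max_examples=50, derandomize=True)
    def test_methods_agree_to_first_order_for_small_p(self, hr):
        p = 1e-6
        a = adjust_probability(p, hr, "rate_transform")
        b = adjust_probability(p, hr, "probability_multiply")
        assert a == pytest.approx(b, rel=1e-4)


class TestTransitionMatrix:
    def test_all_zero_inputs_no_event_limit(self, toy_factory):
        """With every incidence and mortality at zero nothing moves except
        the SAE tunnels, which always empty back to healthy."""
        b = toy_factory()
        M = build_transition_matrix(50, b.strategies["standard"], b)
        for sid in ("healthy", "mi", "stroke", "hf", "death"):
            i = state_index(sid)
            np.testing.assert_allclose(M[i], np.eye(N_STATES)[i], atol=1e-15)
        for sid in ("syncope", "injurious_fall"):
            assert M[state_index(sid), HEALTHY_I] == 1.0
        # persistent-SAE configuration recovers the full identity matrix
        b.sae_persistent = True
        M2 = build_transition_matrix(50, b.strategies["standard"], b)
        np.testing.assert_allclose(M2, np.eye(N_STATES), atol=1e-15)

    def test_single_competing_risk(self, toy_factory):
        b = toy_factory(incidence={"stroke": 0.3})
        M = build_transition_matrix(60, b.strategies["standard"], b)
        assert M[HEALTHY_I, HEALTHY_I] == pytest.approx(0.7, abs=1e-12)
        assert M[HEALTHY_I, state_index("stroke")] == pytest.approx(0.3, abs=1e-12)

    def test_two_competing_risks_rate_allocation(self, toy_factory):
        """Closed form: stay = (1-p1)(1-p2); events split proportional to
        r_i = -ln(1-p_i)."""
        b = toy_factory(incidence={"hypotension": 0.1, "stroke": 0.2})
        M = build_transition_matrix(55, b.strategies["standard"], b)
        r1, r2 = -math.log(0.9), -math.log(0.8)
        total_event = 1.0 - 0.9 * 0.8
        assert M[HEALTHY_I, HEALTHY_I] == pytest.approx(0.72, abs=1e-12)
        assert M[HEALTHY_I, state_index("hypotension")] == pytest.approx(
            total_event * r1 / (r1 + r2), abs=1e-12)  # 0.089813...
        assert M[HEALTHY_I, state_index("stroke")] == pytest.approx(
            total_event * r2 / (r1 + r2), abs=1e-12)  # 0.190187...

    def test_direct_sum_method_matches_raw_probabilities(self, toy_factory):
        b = toy_factory(incidence={"hypotension": 0.1, "stroke": 0.2})
        b.competing_risk_method = CompetingRiskMethod.DIRECT_SUM
        M = build_transition_matrix(55, b.strategies["standard"], b)
        assert M[HEALTHY_I, HEALTHY_I] == pytest.approx(0.7)
        assert M[HEALTHY_I, state_index("stroke")] == pytest.approx(0.2)

    def test_direct_sum_rejects_probabilities_summing_past_one(self, toy_factory):
        b = toy_factory(incidence={"injurious_fall": 0.7, "hf": 0.5})
        b.competing_risk_method = CompetingRiskMethod.DIRECT_SUM
        with pytest.raises(errors.ModelConstructionError):
            build_transition_matrix(55, b.strategies["standard"], b)

    def test_rate_method_valid_even_when_probabilities_sum_past_one(self, toy_factory):
        b = toy_factory(incidence={"injurious_fall": 0.7, "hf": 0.5})
        M = build_transition_matrix(55, b.strategies["standard"], b)
        assert np.all(M >= 0) and np.all(M <= 1)
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_sae_states_are_one_cycle_tunnels(self, bundle):
        M = build_transition_matrix(70, bundle.strategies["standard"], bundle)
        i = state_index("syncope")
        assert M[i, HEALTHY_I] + M[i, DEATH_I] == pytest.approx(1.0)
        assert M[i, i] == 0.0

    def test_cvd_states_persist_until_death(self, bundle):
        M = build_transition_matrix(70, bundle.strategies["standard"], bundle)
        i = state_index("hf")
        assert M[i, i] + M[i, DEATH_I] == pytest.approx(1.0)
        assert M[i, HEALTHY_I] == 0.0

    def test_intensive_arm_applies_event_and_death_hazard_ratios(self, bundle):
        age = 75
        std = build_transition_matrix(age, bundle.strategies["standard"], bundle)
        inten = build_transition_matrix(age, bundle.strategies["intensive"], bundle)
        # acute renal failure HR 1.46 > 1: more ARF transitions
        arf = state_index("acute_renal_failure")
        assert inten[HEALTHY_I, arf] > std[HEALTHY_I, arf]
        # CVD-death HR 0.57 < 1: less mortality from CVD states
        hf = state_index("hf")
        assert inten[hf, DEATH_I] < std[hf, DEATH_I]
        # non-CVD-death HR 0.72 < 1: less mortality from SAE states
        fall = state_index("injurious_fall")
        assert inten[fall, DEATH_I] < std[fall, DEATH_I]

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_rows_stochastic_on_random_bundles(self, seed):
        b = generate_param_set(SynthSpec(seed=seed, mode="range_sample"))
        for age in (50, 75, 100):
            for strat in b.strategies.values():
                M = build_transition_matrix(age, strat, b)
                np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
                assert np.all(M >= 0) and np.all(M <= 1)
                np.testing.assert_array_equal(M[DEATH_I],
                                              np.eye(N_STATES)[DEATH_I])


class TestCohortTrace:
    def test_geometric_toy_closed_form(self, toy_factory):
        """Alive->death at 0.5/cycle, 100 USD and 1 QALY per live cycle:
        undiscounted totals are the geometric sums 200 and 2."""
        b = toy_factory(mortality={"hypertension": 0.5},
                        costs={"hypertension": 100.0}, max_age=150)
        tr = run_cohort(50, b.strategies["standard"], b)
        assert tr.total_cost == pytest.approx(200.0, rel=1e-6)
        assert tr.total_qaly == pytest.approx(2.0, rel=1e-6)

    def test_discounted_cycle_one_value(self, toy_factory):
        b = toy_factory(mortality={"hypertension": 0.5},
                        costs={"hypertension": 100.0})
        b.economics.discount_rate = 0.05
        tr = run_cohort(50, b.strategies["standard"], b)
        assert tr.cost_disc[1] == pytest.approx(100 * 0.5 / 1.05)

    def test_zero_rate_discounted_equals_undiscounted(self, bundle):
        bundle.economics.discount_rate = 0.0
        tr = run_cohort(50, bundle.strategies["standard"], bundle)
        assert tr.total_cost_disc == pytest.approx(tr.total_cost, rel=1e-12)
        assert tr.total_qaly_disc == pytest.approx(tr.total_qaly, rel=1e-12)

    def test_start_age_out_of_range(self, bundle):
        with pytest.raises(errors.DomainError):
            run_cohort(49, bundle.strategies["standard"], bundle)
        with pytest.raises(errors.DomainError):
            run_cohort(101, bundle.strategies["standard"], bundle)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_occupancy_simplex_and_death_monotone(self, seed):
        b = generate_param_set(SynthSpec(seed=seed, mode="range_sample"))
        for strat in b.strategies.values():
            tr = run_cohort(50, strat, b)
            np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0, atol=1e-9)
            death = tr.occupancy[:, DEATH_I]
            assert np.all(np.diff(death) >= -1e-15)

    def test_discount_monotonicity(self, bundle):
        totals = []
        for r in (0.03, 0.05, 0.07):
            bundle.economics.discount_rate = r
            tr = run_cohort(50, bundle.strategies["standard"], bundle)
            totals.append((tr.total_cost_disc, tr.total_qaly_disc))
        assert totals[0][0] > totals[1][0] > totals[2][0]
        assert totals[0][1] > totals[1][1] > totals[2][1]

    def test_trace_dataframe_round_trip(self, bundle, tmp_path):
        tr = run_cohort(50, bundle.strategies["standard"], bundle)
        p = tmp_path / "trace.csv"
        tr.to_dataframe().to_csv(p, index=False)
        import pandas as pd
        df = pd.read_csv(p)
        assert list(df["cycle"]) == list(range(len(tr.ages)))
        np.testing.assert_allclose(df["cost_disc"].sum(), tr.total_cost_disc)


class TestPathEnumerationOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_cohort_totals_equal_exhaustive_path_sum(self, seed):
        """Probability-weighted sum over all two-cycle state paths must equal
        the cohort recursion exactly."""
        b = generate_param_set(SynthSpec(seed=seed, mode="range_sample"))
        b.economics.max_age = 52  # ages 50, 51, 52 -> transitions at 50, 51
        for c in b.age_curves.values():
            c.age_max = 52
            c.values = c.values[:3]
        b.economics.discount_rate = 0.05
        for strat in b.strategies.values():
            tr = run_cohort(50, strat, b)
            M0 = build_transition_matrix(50, strat, b)
            M1 = build_transition_matrix(51, strat, b)
            cvecs = [state_cost_vector(a, strat, b) for a in (50, 51, 52)]
            util = b.utilities.vector()
            d = 1.0 / 1.05
            cost = qaly = 0.0
            h = HEALTHY_I
            for s1, s2 in itertools.product(range(N_STATES), repeat=2):
                w = M0[h, s1] * M1[s1, s2]
                if w == 0.0:
                    continue
                cost += w * (cvecs[0][h] + d * cvecs[1][s1] + d * d * cvecs[2][s2])
                qaly += w * (util[h] + d * util[s1] + d * d * util[s2])
            assert tr.total_cost_disc == pytest.approx(cost, rel=1e-12)
            assert tr.total_qaly_disc == pytest.approx(qaly, rel=1e-12)


class TestStrategyPair:
    def test_identical_arms_when_no_hrs_and_unit_multiplier(self, bundle):
        bundle.strategies["intensive"].hazard_ratios = {}
        bundle.strategies["intensive"].healthy_cost_multiplier = 1.0
        std, inten = run_strategy_pair(bundle)
        np.testing.assert_allclose(std.occupancy, inten.occupancy, atol=0)
        assert std.total_cost_disc == inten.total_cost_disc
        assert std.total_qaly_disc == inten.total_qaly_disc

    def test_protective_death_hrs_increase_qalys(self, bundle):
        for target, hr in bundle.hazard_ratios.items():
            if target not in ("cvd_death", "non_cvd_death"):
                hr.point = 1.0
        bundle.strategies["intensive"].healthy_cost_multiplier = 1.0
        std, inten = run_strategy_pair(bundle)
        assert inten.total_qaly_disc >= std.total_qaly_disc

    def test_multiplier_scales_only_healthy_accruals(self, bundle):
        bundle.strategies["intensive"].hazard_ratios = {}
        std, inten = run_strategy_pair(bundle)
        np.testing.assert_allclose(std.occupancy, inten.occupancy, atol=0)
        healthy_cost = np.array(
            [bundle.curve("cost_hypertension").value_at(a) for a in std.ages])
        extra = 0.2 * (std.occupancy[:, HEALTHY_I] * healthy_cost).sum()
        assert inten.total_cost - std.total_cost == pytest.approx(extra, rel=1e-12)
        assert inten.total_qaly == std.total_qaly


class TestMicrosim:
    def test_degenerate_chain_matches_cohort_exactly(self, toy_factory):
        b = toy_factory(mortality={"hypertension": 1.0},
                        costs={"hypertension": 250.0})
        b.competing_risk_method = CompetingRiskMethod.DIRECT_SUM
        tr = run_cohort(50, b.strategies["standard"], b)
        ms = microsim_oracle(b, None, b.strategies["standard"], 1, seed=0)
        assert ms["mean_cost"] == tr.total_cost_disc
        assert ms["mean_qaly"] == tr.total_qaly_disc

    def test_same_seed_identical_output(self, bundle):
        a = microsim_oracle(bundle, None, bundle.strategies["standard"], 500, 42)
        b = microsim_oracle(bundle, None, bundle.strategies["standard"], 500, 42)
        assert a == b

    def test_invalid_n(self, bundle):
        with pytest.raises(errors.DomainError):
            microsim_oracle(bundle, None, bundle.strategies["standard"], 0, 1)
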