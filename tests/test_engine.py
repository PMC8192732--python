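"""Cohort propagation: hand oracles, matrix oracle, conservation laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiflow.engine import (annual_surgeries, simulate_cohort,
                            steady_state_cross_section, surgery_ledger)
from epiflow.parameters import bundled_scenario, perturb_parameter
from epiflow.plan import (TransitionPlan, WindowedTransition,
                          build_transition_plan)
from epiflow.states import ALL_STATES, HealthState
from epiflow.synth import generate_perturbed_scenarios

from conftest import make_params


def _simulate(params):
    return simulate_cohort(build_transition_plan(params), params)


class TestHandOracles:
    def test_frozen_cohort_stays_in_entry_state(self):
        params = make_params(incident_cohort_size=7117.0, horizon_years=79.3982)
        trace = _simulate(params)
        assert np.allclose(trace.occupancy_of(HealthState.NS_MONO), 7117.0)
        cs = steady_state_cross_section(trace)
        assert cs[HealthState.NS_MONO] == pytest.approx(7117 * 79.3982)
        assert round(cs[HealthState.NS_MONO]) == 565_077
        assert all(cs[s] == 0 for s in ALL_STATES if s != HealthState.NS_MONO)

    def test_single_escalation_branch_two_state_oracle(self):
        # 100 patients, mono -> two-drug with probability 0.5 applied at
        # the start of the cycle after entry; hand-computed trace:
        # cycle 1: all in NS_MONO; cycles 2..: an even split.
        params = make_params(esc_ns=(0.5, 0.0, 0.0), horizon_years=3.0)
        trace = _simulate(params)
        assert trace.occupancy_of(HealthState.NS_MONO).tolist() == [100.0, 50.0, 50.0]
        assert trace.occupancy_of(HealthState.NS_TWO).tolist() == [0.0, 50.0, 50.0]

    def test_escalation_chain_timing(self):
        # deterministic escalation: the cohort moves one line per cycle
        params = make_params(esc_ns=(1.0, 1.0, 1.0), horizon_years=5.0)
        trace = _simulate(params)
        occ = trace.occupancy
        for cycle, state in enumerate([HealthState.NS_MONO, HealthState.NS_TWO,
                                       HealthState.NS_THREE, HealthState.NS_FOUR,
                                       HealthState.NS_FOUR]):
            expected = np.zeros(len(ALL_STATES))
            expected[ALL_STATES.index(state)] = 100.0
            assert np.allclose(occ[cycle], expected)

    def test_windowed_late_referral_decay(self):
        # all mass reaches NS_FOUR at cycle 4, then leaks 10%/cycle into
        # the difficult pool for the 40-year window
        params = make_params(esc_ns=(1.0, 1.0, 1.0), late_referral_annual=0.1,
                             horizon_years=8.0)
        trace = _simulate(params)
        four = trace.occupancy_of(HealthState.NS_FOUR)
        assert four[3] == pytest.approx(100.0)
        assert four[4] == pytest.approx(90.0)
        assert four[7] == pytest.approx(100 * 0.9 ** 4)
        diff = trace.occupancy_of(HealthState.SC_DIFFICULT)
        assert diff[4] == pytest.approx(10.0)
        assert diff[5] == pytest.approx(19.0)

    def test_surgery_deposits_into_outcome_states_next_cycle(self):
        # referral 1.0 then surgery branch 0.5 at the specialized entry:
        # cycle 1 NS_MONO, cycle 2 SC_MONO, cycle 3 surgery (50) + settled
        # SC_MONO (50), cycle 4 post-surgical outcomes
        params = make_params(referral=(1.0, 0.0, 0.0),
                             surg_at_transition=(0.5, 0.0, 0.0),
                             surgery_type_split=(1.0, 0.5, 0.5),
                             horizon_years=4.0)
        trace = _simulate(params)
        assert trace.surgery_events[2, 0] == pytest.approx(50.0)
        assert trace.occupancy[2].sum() == pytest.approx(50.0)  # rest of cohort
        assert trace.occupancy_of(HealthState.PS_FREE)[3] == pytest.approx(50 * 0.53)
        assert trace.occupancy_of(HealthState.PS_REDUCTION)[3] == \
            pytest.approx(50 * 0.47 * 0.73)
        assert trace.occupancy_of(HealthState.PS_DIFFICULT)[3] == \
            pytest.approx(50 * 0.47 * 0.27)

    def test_counter_referral_tunnel_five_annual_chances(self):
        # with no specialized entry branch the cohort settles on arrival
        # (cycle 2); 10%/year counter-referral then applies for exactly
        # five cycles (3..7) and freezes afterwards
        params = make_params(referral=(1.0, 0.0, 0.0),
                             counter_referral_annual=(0.1, 0.0, 0.0),
                             horizon_years=12.0)
        trace = _simulate(params)
        sc = trace.occupancy_of(HealthState.SC_MONO)
        assert sc[1] == pytest.approx(100.0)   # arrival/settling cycle
        for k in range(1, 6):
            assert sc[1 + k] == pytest.approx(100 * 0.9 ** k)
        assert sc[7] == sc[11] == pytest.approx(100 * 0.9 ** 5)
        ns = trace.occupancy_of(HealthState.NS_MONO)
        assert ns[2] == pytest.approx(10.0)    # first counter-referrals
        assert ns[11] == pytest.approx(100 * (1 - 0.9 ** 5))

    def test_fractional_terminal_cycle_weight(self):
        params = make_params(horizon_years=2.4)
        trace = _simulate(params)
        assert trace.n_cycles == 3
        assert trace.cycle_weights.tolist() == [1.0, 1.0, pytest.approx(0.4)]
        cs = steady_state_cross_section(trace)
        assert cs[HealthState.NS_MONO] == pytest.approx(100 * 2.4)


class TestMatrixOracle:
    def test_window_free_plan_matches_matrix_powers(self):
        # A time-homogeneous plan (annual transitions with unbounded
        # windows, no entry branches) must agree with explicit matrix
        # powers to 1e-10 per cell.
        inf = math.inf
        rates = [
            (HealthState.NS_MONO, HealthState.NS_TWO, 0.30),
            (HealthState.NS_MONO, HealthState.SC_MONO, 0.05),
            (HealthState.NS_TWO, HealthState.NS_THREE, 0.20),
            (HealthState.NS_TWO, HealthState.SC_TWO, 0.10),
            (HealthState.SC_MONO, HealthState.SC_TWO, 0.15),
        ]
        plan = TransitionPlan(
            entry_branches={},
            windowed_annual=tuple(
                WindowedTransition(src, dst, p, (1.0, inf)) for src, dst, p in rates
            ),
            tunnel_length=0,
        )
        params = make_params(incident_cohort_size=1000.0, horizon_years=25.0)
        trace = simulate_cohort(plan, params)

        n = len(ALL_STATES)
        P = np.eye(n)
        for src, dst, p in rates:
            i, j = ALL_STATES.index(src), ALL_STATES.index(dst)
            P[i, i] -= p
            P[i, j] += p
        v = np.zeros(n)
        v[ALL_STATES.index(HealthState.NS_MONO)] = 1000.0
        for t in range(trace.n_cycles):
            assert np.max(np.abs(trace.occupancy[t] - v)) < 1e-10
            v = v @ P


class TestConservation:
    @pytest.mark.parametrize("scenario", ["current", "optimized"])
    def test_every_cycle_conserves_the_cohort(self, scenario):
        params, _ = bundled_scenario(scenario)
        trace = _simulate(params)
        totals = trace.occupancy.sum(axis=1) + trace.surgery_events.sum(axis=1)
        assert np.allclose(totals, params.incident_cohort_size, atol=1e-8)

    def test_cross_section_grand_total(self, current_scenario):
        params, _ = current_scenario
        trace = _simulate(params)
        cs = steady_state_cross_section(trace)
        total = sum(cs.values()) + sum(annual_surgeries(trace).values())
        assert total == pytest.approx(
            params.incident_cohort_size * params.horizon_years)

    def test_conservation_over_perturbed_scenario_family(self, current_scenario):
        for params, _ in generate_perturbed_scenarios(
                current_scenario, n=10, spread=0.15, seed=7):
            trace = _simulate(params)
            totals = trace.occupancy.sum(axis=1) + trace.surgery_events.sum(axis=1)
            assert np.allclose(totals, params.incident_cohort_size, atol=1e-8)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_conservation_under_random_jitter(self, current_scenario, seed):
        (params, _), = generate_perturbed_scenarios(
            current_scenario, n=1, spread=0.3, seed=seed)
        trace = _simulate(params)
        totals = trace.occupancy.sum(axis=1) + trace.surgery_events.sum(axis=1)
        assert np.allclose(totals, params.incident_cohort_size, atol=1e-8)
        assert trace.occupancy.min() >= 0


class TestStructuralProperties:
    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_referral_monotonicity(self, current_scenario, k):
        params, _ = current_scenario
        base = steady_state_cross_section(_simulate(params))
        more = steady_state_cross_section(
            _simulate(perturb_parameter(params, f"referral[{k}]", 1.1)))
        sc_states = [HealthState.SC_MONO, HealthState.SC_TWO, HealthState.SC_THREE,
                     HealthState.SC_REDUCTION, HealthState.SC_DIFFICULT]
        assert sum(more[s] for s in sc_states) >= sum(base[s] for s in sc_states)
        assert more[HealthState.NS_FOUR] <= base[HealthState.NS_FOUR]

    def test_scale_equivariance_in_cohort_size(self, current_scenario):
        params, _ = current_scenario
        small = _simulate(params)
        big = _simulate(perturb_parameter(params, "incident_cohort_size", 2.0))
        assert np.allclose(big.occupancy, 2.0 * small.occupancy)
        assert np.allclose(big.surgery_events, 2.0 * small.surgery_events)


class TestSurgeryLedger:
    def test_zero_surgery_plan_reports_undefined_share(self, toy_params):
        ledger = surgery_ledger(_simulate(toy_params))
        assert ledger.total == 0.0
        assert ledger.early_share is None

    def test_current_flow_ledger_structure(self, current_result):
        ledger = surgery_ledger(current_result.trace)
        assert set(ledger.by_line) == {1, 2, 3, "successive"}
        assert all(v > 0 for v in ledger.by_line.values())
        assert ledger.early + ledger.by_line["successive"] == \
            pytest.approx(ledger.total)
        # late operations dominate the current flow
        assert ledger.by_line["successive"] > ledger.early

    def test_optimized_flow_is_early_phase_dominated(self, optimized_result):
        ledger = surgery_ledger(optimized_result.trace)
        assert ledger.early_share > 0.5


def test_trace_frame_is_tidy(current_result):
    frame = current_result.trace.to_frame()
    assert set(frame.columns) == {"cycle", "state", "count"}
    n_cycles = current_result.trace.n_cycles
    assert len(frame) == n_cycles * (len(ALL_STATES) + 4)
    assert frame["count"].min() >= 0
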