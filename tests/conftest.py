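"""Shared fixtures: bundled scenarios, simulated results, synthetic claims."""

from __future__ import annotations

import dataclasses

import pytest

from epiflow.budget import compare_scenarios, run_scenario
from epiflow.parameters import (CostTable, ParameterSet, PostsurgeryOutcome,
                                bundled_scenario)


@pytest.fixture(scope="session")
def current_scenario():
    return bundled_scenario("current")


@pytest.fixture(scope="session")
def optimized_scenario():
    return bundled_scenario("optimized")


@pytest.fixture(scope="session")
def current_result(current_scenario):
    return run_scenario(*current_scenario)


@pytest.fixture(scope="session")
def optimized_result(optimized_scenario):
    return run_scenario(*optimized_scenario)


@pytest.fixture(scope="session")
def budget_report(current_scenario, optimized_scenario):
    return compare_scenarios(current_scenario, optimized_scenario)


def make_params(**overrides) -> ParameterSet:
    """A minimal valid ParameterSet; all transition probabilities zero
    unless overridden (frozen-cohort baseline for hand oracles)."""
    defaults = dict(
        incident_cohort_size=100.0,
        esc_ns=(0.0, 0.0, 0.0),
        esc_sc=(0.0, 0.0, 0.0),
        referral=(0.0, 0.0, 0.0),
        surg_at_transition=(0.0, 0.0, 0.0),
        late_referral_annual=0.0,
        late_surgery_annual=0.0,
        counter_referral_annual=(0.0, 0.0, 0.0),
        surgery_type_split=(0.5, 0.5, 0.5),
        postsurgery_outcome=(PostsurgeryOutcome(0.53, 0.73),
                             PostsurgeryOutcome(0.075, 0.20)),
        horizon_years=10.0,
    )
    defaults.update(overrides)
    return ParameterSet(**defaults)


def make_costs(ns_value: float = 0.0, sc_value: float = 0.0,
               surgery_value: float = 0.0, **overrides) -> CostTable:
    """A uniform cost table (every band the same) for toy scenarios."""
    bands = ("ped_le6", "ped_gt6", "adult")
    defaults = dict(
        pharma_3mo={
            "non-specialized": {row: {b: ns_value for b in bands}
                                for row in ("mono", "two", "three", "four")},
            "specialized": {row: {b: sc_value for b in bands}
                            for row in ("mono", "two", "three",
                                        "reduction", "difficult")},
        },
        surgery={b: surgery_value for b in ("le9", "10_14", "15_19", "adult")},
    )
    defaults.update(overrides)
    return CostTable(**defaults)


@pytest.fixture
def toy_params():
    return make_params()


@pytest.fixture(scope="session")
def synthetic_claims_20k():
    """Large synthetic claims extract with the current-flow escalation
    probabilities as ground truth (shared: generation is the slow part)."""
    from epiflow.synth import generate_prescription_records

    truth = (0.386, 0.271, 0.235)
    records = generate_prescription_records(20_000, true_probs=truth, seed=42)
    return truth, records
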