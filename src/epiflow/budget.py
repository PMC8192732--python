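"""Costing and budget-impact comparison of two treatment-flow scenarios.

Attaches the age-banded cost tables to a cohort trace and reproduces the
layout of the published base-case tables: the patient-distribution table
(annual national cross-section by state) and the annual-cost table in
million JPY, each with current-flow, optimized-flow and difference
columns, plus the headline budget impact.

Conventions (see docs/methods.md for the full account):

* annual pharmacotherapy cost = 4 x the 3-month cost; the age band of a
  cycle uses age at the start of the cycle (age = 4 + cycle);
* post-surgical patients are costed in a separate "after surgery" block —
  seizure-free patients at the specialized-care monotherapy rate, the
  seizure-reduction and difficult-to-treat outcomes at the corresponding
  specialized-care rates;
* a surgery is costed as the operation fee plus one year of
  pharmacotherapy at the origin state's rate (the operation occupies one
  patient-cycle);
* in the patient-distribution table, post-surgical patients are carried
  inside the printed rows: seizure-free in non-specialized monotherapy
  (primary-care maintenance), the other two outcomes in the specialized
  seizure-reduction and difficult-to-treat rows.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .engine import (SURGERY_ORIGIN, CohortTrace, annual_surgeries,
                     simulate_cohort, steady_state_cross_section)
from .parameters import CostTable, ParameterSet
from .plan import build_transition_plan
from .states import ALL_STATES, HealthState

#: Occupancy state -> (care setting, cost row) in the 3-month cost table.
_COST_ROW = {
    HealthState.NS_MONO: ("non-specialized", "mono"),
    HealthState.NS_TWO: ("non-specialized", "two"),
    HealthState.NS_THREE: ("non-specialized", "three"),
    HealthState.NS_FOUR: ("non-specialized", "four"),
    HealthState.SC_MONO: ("specialized", "mono"),
    HealthState.SC_TWO: ("specialized", "two"),
    HealthState.SC_THREE: ("specialized", "three"),
    HealthState.SC_REDUCTION: ("specialized", "reduction"),
    HealthState.SC_DIFFICULT: ("specialized", "difficult"),
    HealthState.PS_FREE: ("specialized", "mono"),
    HealthState.PS_REDUCTION: ("specialized", "reduction"),
    HealthState.PS_DIFFICULT: ("specialized", "difficult"),
}


def annual_state_cost(state: HealthState, age: float, costs: CostTable) -> float:
    """Annual pharmacotherapy cost (JPY/year) of one patient in ``state``."""
    try:
        setting, row = _COST_ROW[state]
    except KeyError:
        raise KeyError(f"{state!r} is not an occupancy state") from None
    band = costs.pharma_band(age)
    try:
        return 4.0 * costs.pharma_3mo[setting][row][band]
    except KeyError:
        raise KeyError(
            f"no cost configured for ({setting}, {row}, {band})"
        ) from None


def surgery_cost(age: float, costs: CostTable) -> float:
    """Per-operation surgery cost (JPY) at the given age."""
    return costs.surgery[costs.surgery_band(age)]


# ---------------------------------------------------------------------
# Single-scenario result
# ---------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ScenarioResult:
    """One simulated scenario with its cross-section and cost breakdown."""

    params: ParameterSet
    costs: CostTable
    trace: CohortTrace
    cross_section: dict[HealthState, float]
    surgeries: dict  # by line: 1, 2, 3, "successive"
    state_cost: dict[HealthState, float]       # JPY/year, occupancy cost
    surgery_block_cost: dict  # by line, JPY/year: operation + surgery-cycle pharma

    @property
    def total_cost(self) -> float:
        return sum(self.state_cost.values()) + sum(self.surgery_block_cost.values())


def run_scenario(params: ParameterSet, costs: CostTable,
                 late_window_clock: str = "entry") -> ScenarioResult:
    """Build the plan, simulate the cohort, and cost the trace."""
    plan = build_transition_plan(params, late_window_clock=late_window_clock)
    trace = simulate_cohort(plan, params)
    return cost_trace(trace, params, costs)


def cost_trace(trace: CohortTrace, params: ParameterSet,
               costs: CostTable) -> ScenarioResult:
    n = trace.n_cycles
    ages = 4.0 + np.arange(1, n + 1)
    w = trace.cycle_weights

    state_cost: dict[HealthState, float] = {}
    for i, state in enumerate(ALL_STATES):
        rates = np.array([annual_state_cost(state, a, costs) for a in ages])
        state_cost[state] = float(np.sum(w * trace.occupancy[:, i] * rates))

    op_rates = np.array([surgery_cost(a, costs) for a in ages])
    surgery_block_cost = {}
    from .states import SURGERY_LINES

    for j, line in enumerate(SURGERY_LINES):
        origin = SURGERY_ORIGIN[line]
        pharma = np.array([annual_state_cost(origin, a, costs) for a in ages])
        surgery_block_cost[line] = float(
            np.sum(w * trace.surgery_events[:, j] * (op_rates + pharma))
        )

    return ScenarioResult(
        params=params,
        costs=costs,
        trace=trace,
        cross_section=steady_state_cross_section(trace),
        surgeries=annual_surgeries(trace),
        state_cost=state_cost,
        surgery_block_cost=surgery_block_cost,
    )


# ---------------------------------------------------------------------
# Published table layouts
# ---------------------------------------------------------------------

_MJPY = 1e-6


def _patient_rows(r: ScenarioResult) -> dict[tuple[str, str], float]:
    cs = r.cross_section
    ns = {
        "mono": cs[HealthState.NS_MONO] + cs[HealthState.PS_FREE],
        "two": cs[HealthState.NS_TWO],
        "three": cs[HealthState.NS_THREE],
        "four": cs[HealthState.NS_FOUR],
    }
    sc = {
        "mono": cs[HealthState.SC_MONO],
        "two": cs[HealthState.SC_TWO],
        "three": cs[HealthState.SC_THREE],
        "reduction": cs[HealthState.SC_REDUCTION] + cs[HealthState.PS_REDUCTION],
        "difficult": cs[HealthState.SC_DIFFICULT] + cs[HealthState.PS_DIFFICULT],
    }
    surgeries = r.surgeries
    rows: dict[tuple[str, str], float] = {}
    rows[("total", "total")] = sum(ns.values()) + sum(sc.values()) + sum(surgeries.values())
    rows[("non-specialized", "subtotal")] = sum(ns.values())
    for key, v in ns.items():
        rows[("non-specialized", key)] = v
    rows[("specialized", "subtotal")] = sum(sc.values())
    for key, v in sc.items():
        rows[("specialized", key)] = v
    rows[("surgery", "annual")] = sum(surgeries.values())
    rows[("surgery", "mono")] = surgeries[1]
    rows[("surgery", "two")] = surgeries[2]
    rows[("surgery", "three_immediate")] = surgeries[3]
    rows[("surgery", "successive_three")] = surgeries["successive"]
    return rows


def _cost_rows(r: ScenarioResult) -> dict[tuple[str, str], float]:
    sc_cost = r.state_cost
    ns = {key: sc_cost[state] * _MJPY for key, state in (
        ("mono", HealthState.NS_MONO), ("two", HealthState.NS_TWO),
        ("three", HealthState.NS_THREE), ("four", HealthState.NS_FOUR))}
    sc = {key: sc_cost[state] * _MJPY for key, state in (
        ("mono", HealthState.SC_MONO), ("two", HealthState.SC_TWO),
        ("three", HealthState.SC_THREE), ("reduction", HealthState.SC_REDUCTION),
        ("difficult", HealthState.SC_DIFFICULT))}
    surgery = {
        "mono": r.surgery_block_cost[1] * _MJPY,
        "two": r.surgery_block_cost[2] * _MJPY,
        "three": (r.surgery_block_cost[3] + r.surgery_block_cost["successive"]) * _MJPY,
    }
    after = {key: sc_cost[state] * _MJPY for key, state in (
        ("seizure_free", HealthState.PS_FREE),
        ("seizure_reduction", HealthState.PS_REDUCTION),
        ("difficult", HealthState.PS_DIFFICULT))}
    rows: dict[tuple[str, str], float] = {}
    rows[("total", "total")] = (sum(ns.values()) + sum(sc.values())
                                + sum(surgery.values()) + sum(after.values()))
    for block, table in (("non-specialized", ns), ("specialized", sc),
                         ("surgery", surgery), ("after-surgery", after)):
        rows[(block, "subtotal")] = sum(table.values())
        for key, v in table.items():
            rows[(block, key)] = v
    return rows


def _table(current: dict, optimized: dict) -> pd.DataFrame:
    index = pd.MultiIndex.from_tuples(current.keys(), names=["block", "row"])
    frame = pd.DataFrame(
        {
            "current": list(current.values()),
            "optimized": [optimized[k] for k in current],
        },
        index=index,
    )
    frame["difference"] = frame["optimized"] - frame["current"]
    return frame


@dataclasses.dataclass(frozen=True)
class BudgetReport:
    """Scenario comparison in the published base-case table layouts."""

    patient_table: pd.DataFrame      # annual patients
    cost_table: pd.DataFrame         # million JPY/year
    current: ScenarioResult
    optimized: ScenarioResult

    @property
    def total_difference_mjpy(self) -> float:
        """Headline budget impact: optimized minus current, million JPY."""
        return float(self.cost_table.loc[("total", "total"), "difference"])

    @property
    def percent_of_current(self) -> float:
        current = float(self.cost_table.loc[("total", "total"), "current"])
        return 100.0 * self.total_difference_mjpy / current

    def summary(self) -> str:
        lines = [
            "Budget impact of treatment-flow optimization",
            "=" * 52,
            "",
            "Annual patient distribution:",
            _format_table(self.patient_table, "{:,.0f}"),
            "",
            "Annual cost (million JPY):",
            _format_table(self.cost_table, "{:,.0f}"),
            "",
            f"Headline: {self.total_difference_mjpy:,.0f} million JPY "
            f"({self.percent_of_current:+.1f}% of the current flow)",
        ]
        return "\n".join(lines)


def _format_table(frame: pd.DataFrame, fmt: str) -> str:
    shown = frame.copy()
    for col in shown.columns:
        shown[col] = shown[col].map(lambda v: fmt.format(v))
    return shown.to_string()


def compare_scenarios(
    current: tuple[ParameterSet, CostTable],
    optimized: tuple[ParameterSet, CostTable],
    late_window_clock: str = "entry",
) -> BudgetReport:
    """Run both scenarios and assemble the budget-impact report.

    Internal arithmetic is kept in full precision; rounding to integer
    patients / million JPY happens only on emission (``summary()`` or the
    CLI's CSV export).
    """
    cur_params, _ = current
    opt_params, _ = optimized
    if cur_params.horizon_years != opt_params.horizon_years:
        raise ValueError(
            "scenario horizons differ "
            f"({cur_params.horizon_years} vs {opt_params.horizon_years}); "
            "the annual comparison is undefined"
        )
    cur = run_scenario(*current, late_window_clock=late_window_clock)
    opt = run_scenario(*optimized, late_window_clock=late_window_clock)
    return BudgetReport(
        patient_table=_table(_patient_rows(cur), _patient_rows(opt)),
        cost_table=_table(_cost_rows(cur), _cost_rows(opt)),
        current=cur,
        optimized=opt,
    )
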