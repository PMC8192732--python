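"""High-level model objects tying the stages together.

:class:`TreatmentFlowModel` binds one scenario's parameters and costs;
``simulate()`` returns a :class:`CohortResults` carrying the trace, the
annual cross-section, the surgery ledger and the cost breakdown, with a
``summary()`` table.  :class:`BudgetImpact` compares two flows.
"""

from __future__ import annotations

import dataclasses

from . import budget as _budget
from .budget import BudgetReport, ScenarioResult
from .engine import surgery_ledger
from .parameters import (CostTable, ParameterSet, bundled_scenario,
                         load_scenario)
from .plan import TransitionPlan, build_transition_plan
from .states import ALL_STATES


class TreatmentFlowModel:
    """One treatment-flow scenario of the epilepsy referral cohort model."""

    def __init__(self, params: ParameterSet, costs: CostTable,
                 name: str = "scenario",
                 late_window_clock: str = "entry") -> None:
        self.params = params
        self.costs = costs
        self.name = name
        self.late_window_clock = late_window_clock

    @classmethod
    def from_file(cls, path, scenario_name: str, **kwargs) -> "TreatmentFlowModel":
        params, costs = load_scenario(path, scenario_name)
        return cls(params, costs, name=scenario_name, **kwargs)

    @classmethod
    def from_bundled(cls, scenario_name: str, **kwargs) -> "TreatmentFlowModel":
        """The packaged "current" or "optimized" published flow."""
        params, costs = bundled_scenario(scenario_name)
        return cls(params, costs, name=scenario_name, **kwargs)

    @property
    def plan(self) -> TransitionPlan:
        return build_transition_plan(self.params,
                                     late_window_clock=self.late_window_clock)

    def simulate(self) -> "CohortResults":
        result = _budget.run_scenario(self.params, self.costs,
                                      late_window_clock=self.late_window_clock)
        return CohortResults(model=self, result=result)


@dataclasses.dataclass(frozen=True)
class CohortResults:
    """Simulated scenario: trace, cross-section, surgeries, and costs."""

    model: TreatmentFlowModel
    result: ScenarioResult

    @property
    def trace(self):
        return self.result.trace

    @property
    def cross_section(self):
        return self.result.cross_section

    @property
    def surgeries(self):
        return self.result.surgeries

    @property
    def ledger(self):
        return surgery_ledger(self.result.trace)

    @property
    def total_cost_mjpy(self) -> float:
        return self.result.total_cost * 1e-6

    def summary(self) -> str:
        cs = self.result.cross_section
        lines = [
            f"Treatment flow scenario: {self.model.name}",
            "=" * 48,
            f"incident cohort  {self.model.params.incident_cohort_size:,.0f} patients/year",
            f"horizon          {self.model.params.horizon_years:g} years",
            "",
            "annual cross-section (patients):",
        ]
        for state in ALL_STATES:
            lines.append(f"  {state.value:14s} {cs[state]:12,.0f}")
        ledger = self.ledger
        lines += [
            "",
            f"annual surgeries {ledger.total:10,.1f}",
            f"  early phase    {ledger.early:10,.1f}"
            + (f"  ({100 * ledger.early_share:.1f}%)"
               if ledger.early_share is not None else ""),
            "",
            f"annual cost      {self.total_cost_mjpy:12,.0f} million JPY",
        ]
        return "\n".join(lines)


class BudgetImpact:
    """Budget-impact comparison of a current and an optimized flow."""

    def __init__(self, current: TreatmentFlowModel,
                 optimized: TreatmentFlowModel) -> None:
        self.current = current
        self.optimized = optimized

    @classmethod
    def from_bundled(cls) -> "BudgetImpact":
        return cls(TreatmentFlowModel.from_bundled("current"),
                   TreatmentFlowModel.from_bundled("optimized"))

    def run(self) -> BudgetReport:
        return _budget.compare_scenarios(
            (self.current.params, self.current.costs),
            (self.optimized.params, self.optimized.costs),
            late_window_clock=self.current.late_window_clock,
        )
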