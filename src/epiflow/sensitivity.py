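"""One-way sensitivity analysis with tornado ordering.

Every scalar clinical parameter of each flow, and every cost entry, is
perturbed to a low and a high bound while everything else stays at base,
and the headline budget impact (total annual cost difference, optimized
minus current, in million JPY) is recomputed.  Rows are sorted by the
width of the induced headline range — the tornado diagram order.

Two bound constructions are supported because the source analysis states
both without reconciling them:

* ``pct20`` (default): value x 0.8 and x 1.2;
* ``ci95``: value ± 1.96 x SE with SE = 0.1 x value, i.e. x(1 ± 0.196).

Clinical parameters of the two flows are perturbed independently (one row
per flow and parameter).  Cost entries and the incident cohort size are
shared between the flows, so they are perturbed jointly in a single row —
perturbing a national price or the national incidence for only one
scenario would not describe a coherent comparison.
"""

from __future__ import annotations

import dataclasses

from .budget import run_scenario
from .parameters import (CostTable, ParameterSet, perturb_cost,
                         perturb_parameter)

_MJPY = 1e-6

_FACTORS = {
    "pct20": (0.8, 1.2),
    "ci95": (1.0 - 1.96 * 0.1, 1.0 + 1.96 * 0.1),
}

#: Parameter paths perturbed jointly for both flows.
_JOINT_PARAMS = ("incident_cohort_size",)


@dataclasses.dataclass(frozen=True)
class TornadoRow:
    """Headline budget impact at the two bounds of one parameter."""

    parameter: str       # e.g. "current.esc_ns[0]" or "costs.surgery.adult"
    low_value: float     # headline (million JPY) at the low bound
    high_value: float    # headline at the high bound
    base_value: float    # headline at base (same for every row)

    @property
    def range(self) -> float:
        return abs(self.high_value - self.low_value)

    @property
    def worst_case(self) -> float:
        """Headline at the bound minimizing the cost saving."""
        return max(self.low_value, self.high_value)


Scenario = tuple[ParameterSet, CostTable]


def _headline(current: Scenario, optimized: Scenario) -> float:
    cur = run_scenario(*current)
    opt = run_scenario(*optimized)
    return (opt.total_cost - cur.total_cost) * _MJPY


def one_way_tornado(
    current: Scenario,
    optimized: Scenario,
    mode: str = "pct20",
) -> list[TornadoRow]:
    """Tornado rows for every scalar parameter and cost entry, sorted by
    descending headline range."""
    if mode not in _FACTORS:
        raise ValueError(f"mode must be one of {sorted(_FACTORS)}, got {mode!r}")
    lo_f, hi_f = _FACTORS[mode]

    cur_params, cur_costs = current
    opt_params, opt_costs = optimized
    # Totals are additive across flows, so only the perturbed flow is
    # re-simulated for per-flow parameters.
    base_cur = run_scenario(cur_params, cur_costs).total_cost
    base_opt = run_scenario(opt_params, opt_costs).total_cost
    base = (base_opt - base_cur) * _MJPY

    rows: list[TornadoRow] = []

    def flow_row(side: str, path: str) -> TornadoRow:
        params, costs = (cur_params, cur_costs) if side == "current" else (opt_params, opt_costs)
        bounds = []
        for f in (lo_f, hi_f):
            total = run_scenario(perturb_parameter(params, path, f), costs).total_cost
            if side == "current":
                bounds.append((base_opt - total) * _MJPY)
            else:
                bounds.append((total - base_cur) * _MJPY)
        return TornadoRow(f"{side}.{path}", bounds[0], bounds[1], base)

    def joint_param_row(path: str) -> TornadoRow:
        bounds = []
        for f in (lo_f, hi_f):
            bounds.append(_headline(
                (perturb_parameter(cur_params, path, f), cur_costs),
                (perturb_parameter(opt_params, path, f), opt_costs),
            ))
        return TornadoRow(path, bounds[0], bounds[1], base)

    def cost_row(path: str) -> TornadoRow:
        bounds = []
        for f in (lo_f, hi_f):
            bounds.append(_headline(
                (cur_params, perturb_cost(cur_costs, path, f)),
                (opt_params, perturb_cost(opt_costs, path, f)),
            ))
        return TornadoRow(f"costs.{path}", bounds[0], bounds[1], base)

    per_flow = [p for p in cur_params.scalar_paths() if p not in _JOINT_PARAMS]
    for side in ("current", "optimized"):
        for path in per_flow:
            rows.append(flow_row(side, path))
    for path in _JOINT_PARAMS:
        rows.append(joint_param_row(path))
    for path in cur_costs.scalar_paths():
        rows.append(cost_row(path))

    rows.sort(key=lambda r: (-r.range, r.parameter))
    return rows


def tornado_frame(rows: list[TornadoRow]):
    """Tornado table as a DataFrame (parameter, low, high, range, worst)."""
    import pandas as pd

    return pd.DataFrame({
        "parameter": [r.parameter for r in rows],
        "low": [r.low_value for r in rows],
        "high": [r.high_value for r in rows],
        "range": [r.range for r in rows],
        "worst_case": [r.worst_case for r in rows],
    })


def plot_tornado(rows: list[TornadoRow], top: int = 15, ax=None):
    """Horizontal-bar tornado chart of the widest ``top`` rows."""
    import matplotlib.pyplot as plt

    shown = rows[:top][::-1]
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.45 * len(shown) + 1.5))
    base = shown[0].base_value if shown else 0.0
    for i, row in enumerate(shown):
        lo, hi = sorted((row.low_value, row.high_value))
        ax.barh(i, hi - lo, left=lo, color="#4878b0", edgecolor="none")
    ax.axvline(base, color="black", lw=1, ls="--", label="base case")
    ax.set_yticks(range(len(shown)))
    ax.set_yticklabels([r.parameter for r in shown], fontsize=8)
    ax.set_xlabel("budget impact (million JPY, optimized - current)")
    ax.legend(loc="lower right", fontsize=8)
    return ax
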