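"""Deterministic cohort propagation over the lifetime horizon.

One incident cohort (7117 newly diagnosed five-year-olds in the base case)
enters non-specialized monotherapy in cycle 1 and is propagated in annual
cycles as expected patient counts.  Because an identical cohort enters
every year, the annual national cross-section equals the lifetime sum of
one cohort's trace; the terminal fractional cycle is weighted by its
fraction so a non-integer horizon is represented without sub-annual
cycles.

Cycle conventions (reverse-engineered from the published base-case
tables; see docs/methods.md):

* a patient spends at least one full cycle in every state: masses arriving
  in a state during cycle t have their entry branches applied at the start
  of cycle t+1;
* residual (non-branching) mass settles in the state in the branch cycle
  and is exposed to the state's windowed annual transitions from the cycle
  after settling (time-in-state 1);
* surgery is a one-cycle event: the operation occupies its own ledger row
  for one cycle, and survivors are deposited into the post-surgical
  outcome states at the start of the next cycle.

No death is modelled inside the horizon, so every full cycle's total
occupancy (including the surgery row) equals the incident cohort size.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .parameters import ParameterSet
from .plan import TransitionPlan, postsurgery_distribution
from .states import ALL_STATES, SURGERY_LINES, HealthState

_STATE_INDEX = {s: i for i, s in enumerate(ALL_STATES)}
_LINE_INDEX = {line: i for i, line in enumerate(SURGERY_LINES)}

#: Origin occupancy state of each surgery category (used for the surgery
#: cycle's pharmacotherapy costing).
SURGERY_ORIGIN = {
    1: HealthState.SC_MONO,
    2: HealthState.SC_TWO,
    3: HealthState.SC_THREE,
    "successive": HealthState.SC_DIFFICULT,
}


@dataclasses.dataclass(frozen=True)
class CohortTrace:
    """Per-cycle expected occupancy of one incident cohort.

    ``occupancy[t - 1, i]`` is the expected patient count in state
    ``ALL_STATES[i]`` during cycle ``t`` (ages ``4 + t``);
    ``surgery_events[t - 1, j]`` the expected operations performed during
    cycle ``t`` in category ``SURGERY_LINES[j]``.  ``cycle_weights`` are 1
    for full cycles and the residual fraction for the terminal cycle.
    """

    occupancy: np.ndarray
    surgery_events: np.ndarray
    cycle_weights: np.ndarray
    incident_cohort_size: float
    horizon_years: float

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0]

    def occupancy_of(self, state: HealthState) -> np.ndarray:
        return self.occupancy[:, _STATE_INDEX[state]]

    def to_frame(self):
        """Tidy (cycle, state, count) DataFrame export."""
        import pandas as pd

        cycles = np.arange(1, self.n_cycles + 1)
        rows = [
            pd.DataFrame({
                "cycle": cycles,
                "state": state.value,
                "count": self.occupancy[:, i],
            })
            for i, state in enumerate(ALL_STATES)
        ] + [
            pd.DataFrame({
                "cycle": cycles,
                "state": f"surgery@{line}",
                "count": self.surgery_events[:, j],
            })
            for line, j in _LINE_INDEX.items()
        ]
        return pd.concat(rows, ignore_index=True)


def _age_cap(plan: TransitionPlan, state: HealthState) -> int:
    """Smallest time-in-state beyond which window membership is constant."""
    cap = 0
    for w in plan.windowed_from(state):
        if math.isinf(w.window[1]):
            cap = max(cap, int(w.window[0]))
        else:
            cap = max(cap, int(w.window[1]) + 1)
    return cap


def simulate_cohort(plan: TransitionPlan, params: ParameterSet) -> CohortTrace:
    """Propagate one incident cohort and return its lifetime trace."""
    horizon = params.horizon_years
    n_cycles = int(math.ceil(horizon))
    weights = np.ones(n_cycles)
    frac = horizon - math.floor(horizon)
    if frac > 0:
        weights[-1] = frac

    caps = {state: _age_cap(plan, state) for state in ALL_STATES}
    windowed = {state: plan.windowed_from(state) for state in ALL_STATES}
    branches = {state: plan.branches(state) for state in ALL_STATES}
    postsurg = {line: postsurgery_distribution(params, line)
                for line in SURGERY_LINES}

    occupancy = np.zeros((n_cycles, len(ALL_STATES)))
    surgery_events = np.zeros((n_cycles, len(SURGERY_LINES)))

    # Sub-state masses: ("new", state) awaits its entry branch;
    # ("aged", state, a) is settled mass with time-in-state a (capped);
    # ("surgery", line) occupies the surgery ledger for one cycle.
    def arrive(masses: dict, state: HealthState, amount: float) -> None:
        if amount == 0.0:
            return
        key = ("new", state) if branches[state] else ("aged", state, 0)
        masses[key] = masses.get(key, 0.0) + amount

    cur: dict = {}
    arrive(cur, HealthState.NS_MONO, params.incident_cohort_size)
    _record(cur, occupancy, surgery_events, 0)

    for t in range(2, n_cycles + 1):
        prev, cur = cur, {}
        for key, mass in prev.items():
            kind = key[0]
            if kind == "surgery":
                for ps_state, p in postsurg[key[1]].items():
                    arrive(cur, ps_state, mass * p)
            elif kind == "new":
                state = key[1]
                residual = mass
                for b in branches[state]:
                    amount = mass * b.probability
                    residual -= amount
                    if isinstance(b.destination, HealthState):
                        arrive(cur, b.destination, amount)
                    else:
                        line = b.destination[1]
                        cur[("surgery", line)] = cur.get(("surgery", line), 0.0) + amount
                        surgery_events[t - 1, _LINE_INDEX[line]] += amount
                if residual > 0:
                    cur[("aged", state, 0)] = cur.get(("aged", state, 0), 0.0) + residual
            else:  # aged
                state, age = key[1], key[2]
                new_age = min(age + 1, caps[state]) if caps[state] else 0
                residual = mass
                for w in windowed[state]:
                    if not w.active(age + 1, t):
                        continue
                    amount = mass * w.annual_probability
                    residual -= amount
                    if isinstance(w.destination, HealthState):
                        dest = w.destination
                        if (dest.value.startswith("NS_")
                                and not plan.rebranch_on_counter_referral
                                and w.source.value.startswith("SC_")):
                            # counter-referred patients settle as stable
                            akey = ("aged", dest, caps[dest])
                            cur[akey] = cur.get(akey, 0.0) + amount
                        else:
                            arrive(cur, dest, amount)
                    else:
                        line = w.destination[1]
                        cur[("surgery", line)] = cur.get(("surgery", line), 0.0) + amount
                        surgery_events[t - 1, _LINE_INDEX[line]] += amount
                if residual > 0:
                    akey = ("aged", state, new_age)
                    cur[akey] = cur.get(akey, 0.0) + residual
        _record(cur, occupancy, surgery_events, t - 1)

    if not np.isfinite(occupancy).all() or not np.isfinite(surgery_events).all():
        raise RuntimeError("non-finite occupancy encountered in cohort simulation")

    return CohortTrace(
        occupancy=occupancy,
        surgery_events=surgery_events,
        cycle_weights=weights,
        incident_cohort_size=params.incident_cohort_size,
        horizon_years=horizon,
    )


def _record(masses: dict, occupancy: np.ndarray, surgery_events: np.ndarray,
            row: int) -> None:
    for key, mass in masses.items():
        if key[0] == "surgery":
            continue  # already ledgered in surgery_events
        occupancy[row, _STATE_INDEX[key[1]]] += mass


def steady_state_cross_section(trace: CohortTrace) -> dict[HealthState, float]:
    """Annual national cross-section: weighted lifetime sum per state.

    Valid because an identical cohort enters every year, so the annual
    snapshot over all prevalent cohorts equals one cohort's lifetime sum.
    The grand total over states plus the annual surgery count equals
    ``incident_cohort_size x horizon_years``.
    """
    totals = trace.cycle_weights @ trace.occupancy
    return {state: float(totals[i]) for i, state in enumerate(ALL_STATES)}


def annual_surgeries(trace: CohortTrace) -> dict[int | str, float]:
    """Annual operations by category (therapy line at surgery)."""
    totals = trace.cycle_weights @ trace.surgery_events
    return {line: float(totals[j]) for line, j in _LINE_INDEX.items()}


@dataclasses.dataclass(frozen=True)
class SurgeryLedger:
    """Annual surgery counts split by phase of the treatment journey."""

    by_line: dict[int | str, float]

    @property
    def total(self) -> float:
        return sum(self.by_line.values())

    @property
    def early(self) -> float:
        """Operations immediately after mono-, two-, or three-drug therapy."""
        return self.by_line[1] + self.by_line[2] + self.by_line[3]

    @property
    def early_share(self) -> float | None:
        """Early-phase share of all operations; None when there are none."""
        total = self.total
        if total == 0.0:
            return None
        return self.early / total


def surgery_ledger(trace: CohortTrace) -> SurgeryLedger:
    return SurgeryLedger(by_line=annual_surgeries(trace))
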