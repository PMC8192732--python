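"""Transition rules: from a ParameterSet to per-cycle transition structure.

Two kinds of transitions drive the cohort:

* **Entry branches** — applied once, at the start of the cycle after a
  patient enters a therapy state (every patient spends at least one full
  cycle in each state).  At a non-specialized line the branches are
  referral to specialized care at the same line and escalation to the next
  line, competing on the same entry mass.  At a specialized line the
  branches are escalation and diversion to surgery, again competing.
  Residual mass settles in the state.

* **Windowed annual transitions** — applied every cycle while the
  patient's time in the state lies inside a window: late referral of
  non-specialized four-drug patients into the difficult-to-treat pool,
  late surgery (and, where configured, transition to the seizure-reduction
  pool) out of difficult-to-treat, and counter-referral of settled
  specialized-care patients back to primary care (a 5-year tunnel).

The plan is a declarative description; :mod:`epiflow.engine` executes it.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

from .parameters import ParameterSet
from .states import NS_LINES, SC_LINES, HealthState

#: Branch destinations: a health state, or a surgery event tagged with the
#: therapy line at which the operation is performed.
Surgery = tuple[Literal["surgery"], int | str]


def surgery_event(line: int | str) -> Surgery:
    return ("surgery", line)


@dataclasses.dataclass(frozen=True)
class EntryBranch:
    """One competing branch applied at the branch cycle after entry."""

    destination: HealthState | Surgery
    probability: float


@dataclasses.dataclass(frozen=True)
class WindowedTransition:
    """An annual transition active while time-in-state is within a window.

    ``window`` is (first, last) cycle-in-state, 1-based, inclusive; the
    first opportunity to move is one cycle after entering the state.  With
    ``clock="onset"`` the window is measured in model cycles since cohort
    entry instead of cycles in state.  ``math.inf`` encodes an unbounded
    window (a plain time-homogeneous annual transition).
    """

    source: HealthState
    destination: HealthState | Surgery
    annual_probability: float
    window: tuple[float, float]
    clock: Literal["entry", "onset"] = "entry"

    def active(self, age_in_state: int, cycle: int) -> bool:
        t = cycle if self.clock == "onset" else age_in_state
        return self.window[0] <= t <= self.window[1]


@dataclasses.dataclass(frozen=True)
class TransitionPlan:
    """Complete transition structure for one scenario."""

    entry_branches: dict[HealthState, tuple[EntryBranch, ...]]
    windowed_annual: tuple[WindowedTransition, ...]
    tunnel_length: int  # cycles of counter-referral eligibility after settling
    rebranch_on_counter_referral: bool = False

    def branches(self, state: HealthState) -> tuple[EntryBranch, ...]:
        return self.entry_branches.get(state, ())

    def windowed_from(self, state: HealthState) -> tuple[WindowedTransition, ...]:
        return tuple(w for w in self.windowed_annual if w.source == state)

    def validate(self) -> None:
        for state, branches in self.entry_branches.items():
            total = sum(b.probability for b in branches)
            if total > 1.0 + 1e-12:
                raise ValueError(
                    f"entry branches of {state} sum to {total:.6g} > 1"
                )
            if any(b.probability < 0 for b in branches):
                raise ValueError(f"negative branch probability at {state}")
        by_source: dict[HealthState, float] = {}
        for w in self.windowed_annual:
            if not 0.0 <= w.annual_probability <= 1.0:
                raise ValueError(
                    f"annual probability of {w.source}->{w.destination} "
                    "outside [0, 1]"
                )
            by_source[w.source] = by_source.get(w.source, 0.0) + w.annual_probability
        for source, total in by_source.items():
            if total > 1.0 + 1e-12:
                raise ValueError(
                    f"windowed annual outflows of {source} sum to {total:.6g} > 1"
                )

    def to_frame(self):
        """Human-readable transition table for audit export."""
        import pandas as pd

        rows = []
        for state, branches in self.entry_branches.items():
            for b in branches:
                rows.append({
                    "source": state.value,
                    "destination": _dest_label(b.destination),
                    "probability": b.probability,
                    "type": "entry-branch",
                    "window": "",
                })
        for w in self.windowed_annual:
            lo, hi = w.window
            rows.append({
                "source": w.source.value,
                "destination": _dest_label(w.destination),
                "probability": w.annual_probability,
                "type": f"annual ({w.clock} clock)",
                "window": f"{lo:g}-{hi:g}",
            })
        return pd.DataFrame(rows)


def _dest_label(dest: HealthState | Surgery) -> str:
    if isinstance(dest, HealthState):
        return dest.value
    return f"surgery@{dest[1]}"


def build_transition_plan(
    params: ParameterSet,
    late_window_clock: Literal["entry", "onset"] = "entry",
) -> TransitionPlan:
    """Convert a validated ParameterSet into the scenario's TransitionPlan.

    Topology:

    * NS line k entry (k = 1..3): competing branches referral -> SC line k
      and escalation -> NS line k+1.
    * SC line k entry: competing branches escalation (-> SC line k+1, or
      the difficult-to-treat pool for k = 3) and surgery at the transition
      to line k+1.
    * NS four-drug -> difficult-to-treat at ``late_referral_annual`` and
      difficult-to-treat -> surgery ("successive" operations) at
      ``late_surgery_annual``, each year within the 40-year late window;
      ``reduction_inflow_annual`` moves difficult-to-treat patients into
      the specialized seizure-reduction pool on the same window.
    * SC line k -> NS line k at ``counter_referral_annual[k]`` for the
      first ``counter_referral_window_years`` cycles after settling.

    ``late_window_clock`` selects whether the 40-year window is measured
    from entry into the four-drug / difficult-to-treat state (default,
    following the parameter table's heading) or from cohort entry
    ("onset", following the methods prose).
    """
    params.validate()
    entry: dict[HealthState, tuple[EntryBranch, ...]] = {}
    for k in range(3):
        ns_branches = []
        if params.referral[k] > 0:
            ns_branches.append(EntryBranch(SC_LINES[k], params.referral[k]))
        if params.esc_ns[k] > 0:
            ns_branches.append(EntryBranch(NS_LINES[k + 1], params.esc_ns[k]))
        entry[NS_LINES[k]] = tuple(ns_branches)

        sc_dest = SC_LINES[k + 1] if k < 2 else HealthState.SC_DIFFICULT
        sc_branches = []
        if params.esc_sc[k] > 0:
            sc_branches.append(EntryBranch(sc_dest, params.esc_sc[k]))
        if params.surg_at_transition[k] > 0:
            sc_branches.append(
                EntryBranch(surgery_event(k + 1), params.surg_at_transition[k])
            )
        entry[SC_LINES[k]] = tuple(sc_branches)
    entry[HealthState.NS_FOUR] = ()

    late_window = (1.0, params.late_window_years)
    windowed: list[WindowedTransition] = []
    if params.late_referral_annual > 0:
        windowed.append(WindowedTransition(
            HealthState.NS_FOUR, HealthState.SC_DIFFICULT,
            params.late_referral_annual, late_window, late_window_clock,
        ))
    if params.late_surgery_annual > 0:
        windowed.append(WindowedTransition(
            HealthState.SC_DIFFICULT, surgery_event("successive"),
            params.late_surgery_annual, late_window, late_window_clock,
        ))
    if params.reduction_inflow_annual > 0:
        windowed.append(WindowedTransition(
            HealthState.SC_DIFFICULT, HealthState.SC_REDUCTION,
            params.reduction_inflow_annual, late_window, late_window_clock,
        ))
    tunnel = int(math.ceil(params.counter_referral_window_years))
    for k in range(3):
        if params.counter_referral_annual[k] > 0 and tunnel > 0:
            windowed.append(WindowedTransition(
                SC_LINES[k], NS_LINES[k],
                params.counter_referral_annual[k], (1.0, float(tunnel)), "entry",
            ))

    plan = TransitionPlan(
        entry_branches=entry,
        windowed_annual=tuple(windowed),
        tunnel_length=tunnel,
    )
    plan.validate()
    return plan


def postsurgery_distribution(
    params: ParameterSet, line_at_surgery: int | str
) -> dict[HealthState, float]:
    """Distribution over post-surgical outcome states for one operation.

    The curative/palliative mix is the surgery-type split of the therapy
    line at surgery (late operations out of the difficult-to-treat pool
    use the three-drug split).  Within each type the outcome layers are
    conditional: seizure freedom with probability ``freedom``; significant
    seizure reduction with probability ``reduction`` among patients not
    seizure free; the remainder stay difficult to treat.
    """
    if line_at_surgery == "successive":
        line = 3
    else:
        line = int(line_at_surgery)
        if line not in (1, 2, 3):
            raise ValueError(f"line_at_surgery must be 1, 2, 3 or 'successive', "
                             f"got {line_at_surgery!r}")
    curative_share = params.surgery_type_split[line - 1]
    dist = {HealthState.PS_FREE: 0.0,
            HealthState.PS_REDUCTION: 0.0,
            HealthState.PS_DIFFICULT: 0.0}
    for share, outcome in zip((curative_share, 1.0 - curative_share),
                              params.postsurgery_outcome):
        dist[HealthState.PS_FREE] += share * outcome.freedom
        dist[HealthState.PS_REDUCTION] += share * (1.0 - outcome.freedom) * outcome.reduction
        dist[HealthState.PS_DIFFICULT] += share * (1.0 - outcome.freedom) * (1.0 - outcome.reduction)
    return dist
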