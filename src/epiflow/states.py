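"""Health-state space of the epilepsy treatment-flow cohort model.

The model follows newly diagnosed pediatric epilepsy patients through
pharmacotherapy escalation (monotherapy up to four concurrent anti-seizure
medications, ASMs) in two care settings — non-specialized and specialized —
and through epilepsy surgery into three long-term post-surgical outcomes.
Patients enter in non-specialized monotherapy and can only move "forward"
(more drugs, more specialized care, surgery); the single backward flow is
counter-referral of stabilized patients from specialized back to primary
care at the same therapy line.
"""

from __future__ import annotations

import enum


class CareSetting(str, enum.Enum):
    NON_SPECIALIZED = "non-specialized"
    SPECIALIZED = "specialized"
    POST_SURGERY = "post-surgery"


class HealthState(str, enum.Enum):
    """Occupancy states (care setting x therapy line / outcome).

    The identifiers mirror the row structure of the model's patient
    distribution table: four non-specialized therapy lines, three
    specialized therapy lines plus the seizure-reduction and
    difficult-to-treat pools, and three post-surgical outcomes.
    """

    NS_MONO = "NS_MONO"
    NS_TWO = "NS_TWO"
    NS_THREE = "NS_THREE"
    NS_FOUR = "NS_FOUR"
    SC_MONO = "SC_MONO"
    SC_TWO = "SC_TWO"
    SC_THREE = "SC_THREE"
    SC_REDUCTION = "SC_REDUCTION"
    SC_DIFFICULT = "SC_DIFFICULT"
    PS_FREE = "PS_FREE"
    PS_REDUCTION = "PS_REDUCTION"
    PS_DIFFICULT = "PS_DIFFICULT"

    @property
    def care_setting(self) -> CareSetting:
        if self.name.startswith("NS_"):
            return CareSetting.NON_SPECIALIZED
        if self.name.startswith("SC_"):
            return CareSetting.SPECIALIZED
        return CareSetting.POST_SURGERY

    @property
    def therapy_line(self) -> int | None:
        """Number of concurrent ASMs, or None for outcome pools."""
        return {
            "MONO": 1,
            "TWO": 2,
            "THREE": 3,
            "FOUR": 4,
        }.get(self.name.split("_", 1)[1])


#: Therapy-line states by care setting, in escalation order.
NS_LINES = (
    HealthState.NS_MONO,
    HealthState.NS_TWO,
    HealthState.NS_THREE,
    HealthState.NS_FOUR,
)
SC_LINES = (HealthState.SC_MONO, HealthState.SC_TWO, HealthState.SC_THREE)
PS_STATES = (
    HealthState.PS_FREE,
    HealthState.PS_REDUCTION,
    HealthState.PS_DIFFICULT,
)

#: Surgery ledger categories: therapy line at surgery. Lines 1-3 are
#: operations performed immediately at the transition out of that line;
#: "successive" marks late surgery from the difficult-to-treat pool
#: (reported as "in successive three-drug therapy").
SURGERY_LINES = (1, 2, 3, "successive")

ALL_STATES = tuple(HealthState)
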