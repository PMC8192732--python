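"""Estimation of escalation probabilities and combination costs from
outpatient prescription claims.

The non-specialized escalation probabilities of the current treatment
flow are estimated from longitudinal prescription records (patient,
dispensing date, drug, days supplied, price):

* an *episode* starts at the first anti-seizure-medication (ASM)
  prescription preceded by a treatment-free washout (6 months with no ASM
  supply, measured from the end of the last dispensed supply), and is
  followed for 36 months;
* the therapy line is the number of distinct ASMs dispensed on the same
  date; a transition to the next line is an *addition* of ASMs in a
  same-date prescription, so the line is the running maximum of the
  same-date drug count (dropping a drug does not lower the line);
* the line-k escalation probability is the fraction of episodes reaching
  line k that reach line k+1 within follow-up.

Combination costs are frequency-weighted means over observed same-date
drug combinations drawn entirely from a configurable ASM whitelist
(combinations containing any other drug are excluded, as are combinations
of five or more drugs).

Calendar arithmetic uses fixed-length months (6 months = 183 days,
36 months = 1096 days) because claims-database conventions vary.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import math
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375  # 365.25 / 12; 6 months -> 183 d, 36 months -> 1096 d


@dataclasses.dataclass(frozen=True)
class PrescriptionRecord:
    """One dispensing event."""

    patient_id: str
    date: datetime.date
    drug_code: str
    days_supplied: int
    price: float  # JPY for the dispensed supply

    def __post_init__(self) -> None:
        if self.days_supplied <= 0:
            raise ValueError("days_supplied must be positive")
        if self.price < 0:
            raise ValueError("price must be non-negative")


@dataclasses.dataclass(frozen=True)
class TreatmentEpisode:
    """One washout-qualified treatment episode of one patient."""

    patient_id: str
    index_date: datetime.date
    follow_up_end: datetime.date
    #: (date, line) at each line increase, starting with (index_date, n).
    line_history: tuple[tuple[datetime.date, int], ...]

    @property
    def max_line(self) -> int:
        return self.line_history[-1][1]

    def reached(self, line: int) -> bool:
        return self.max_line >= line


def _months_to_days(months: float) -> int:
    return round(months * DAYS_PER_MONTH)


def read_records_csv(path) -> list[PrescriptionRecord]:
    """Load records from CSV (patient_id, date, drug_code, days_supplied,
    price_jpy); unparseable dates are dropped with a logged count."""
    frame = pd.read_csv(path, dtype={"patient_id": str, "drug_code": str})
    records = []
    bad = 0
    for row in frame.itertuples(index=False):
        try:
            date = datetime.date.fromisoformat(str(row.date))
        except ValueError:
            bad += 1
            continue
        records.append(PrescriptionRecord(
            patient_id=str(row.patient_id),
            date=date,
            drug_code=str(row.drug_code),
            days_supplied=int(row.days_supplied),
            price=float(row.price_jpy),
        ))
    if bad:
        logger.warning("dropped %d records with unparseable dates", bad)
    return records


def build_episodes(
    records: Iterable[PrescriptionRecord],
    washout_months: float = 6,
    follow_up_months: float = 36,
    whitelist: set[str] | None = None,
) -> list[TreatmentEpisode]:
    """Construct treatment episodes from dispensing records.

    Only whitelist drugs count as ASMs (all drugs when ``whitelist`` is
    None).  A new episode begins at any prescription with no ASM
    dispensing in the preceding washout window; records after an
    episode's follow-up end are ignored for that episode.  Episodes are
    returned sorted by (patient, index date).
    """
    washout = datetime.timedelta(days=_months_to_days(washout_months))
    follow_up = datetime.timedelta(days=_months_to_days(follow_up_months))

    by_patient: dict[str, list[PrescriptionRecord]] = defaultdict(list)
    for rec in records:
        if whitelist is None or rec.drug_code in whitelist:
            by_patient[rec.patient_id].append(rec)

    episodes: list[TreatmentEpisode] = []
    for patient_id in sorted(by_patient):
        recs = sorted(by_patient[patient_id], key=lambda r: r.date)
        by_date: dict[datetime.date, set[str]] = defaultdict(set)
        supply_end: dict[datetime.date, datetime.date] = {}
        for rec in recs:
            by_date[rec.date].add(rec.drug_code)
            end = rec.date + datetime.timedelta(days=rec.days_supplied)
            if rec.date not in supply_end or end > supply_end[rec.date]:
                supply_end[rec.date] = end
        dates = sorted(by_date)

        # A prescription opens a new episode when the patient has been
        # without ASM supply for longer than the washout (the gap is
        # measured from the end of the last dispensed supply).
        index_dates = []
        covered_until: datetime.date | None = None
        for d in dates:
            if covered_until is None or d - covered_until > washout:
                index_dates.append(d)
            if covered_until is None or supply_end[d] > covered_until:
                covered_until = supply_end[d]
        for index_date in index_dates:
            end = index_date + follow_up
            line = 0
            history: list[tuple[datetime.date, int]] = []
            for d in dates:
                if d < index_date or d > end:
                    continue
                n = len(by_date[d])
                if n > line:  # addition of ASMs in a same-date prescription
                    line = n
                    history.append((d, n))
            episodes.append(TreatmentEpisode(
                patient_id=patient_id,
                index_date=index_date,
                follow_up_end=end,
                line_history=tuple(history),
            ))
    return episodes


@dataclasses.dataclass(frozen=True)
class TransitionEstimate:
    """Escalation probability estimates with audit counts.

    ``probabilities[k]`` is the line k+1 -> k+2 escalation probability
    (None when no episode reached the source line).
    """

    probabilities: tuple[float | None, float | None, float | None]
    numerators: tuple[int, int, int]
    denominators: tuple[int, int, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "transition": ["1->2", "2->3", "3->4"],
            "numerator": self.numerators,
            "denominator": self.denominators,
            "probability": [math.nan if p is None else p
                            for p in self.probabilities],
        })


def estimate_transition_probabilities(
    episodes: Sequence[TreatmentEpisode],
) -> TransitionEstimate:
    """Per-line escalation probabilities from constructed episodes."""
    nums, denoms, probs = [], [], []
    for k in (1, 2, 3):
        denom = sum(1 for e in episodes if e.reached(k))
        num = sum(1 for e in episodes if e.reached(k + 1))
        nums.append(num)
        denoms.append(denom)
        probs.append(num / denom if denom else None)
    return TransitionEstimate(
        probabilities=tuple(probs),
        numerators=tuple(nums),
        denominators=tuple(denoms),
    )


@dataclasses.dataclass(frozen=True)
class CombinationCost:
    """Frequency-weighted mean 3-month combination cost with audit table."""

    n_drugs: int
    mean_cost: float | None  # JPY per 3 months; None without qualifying combos
    frequency_table: pd.DataFrame  # combination, count, mean 3-month cost


def combination_cost(
    records: Iterable[PrescriptionRecord],
    whitelist: set[str],
    n_drugs: int,
) -> CombinationCost:
    """Weighted-average 3-month cost of same-date ``n_drugs`` combinations.

    A same-date prescription qualifies only if it consists of exactly
    ``n_drugs`` distinct drugs, all on the whitelist; prescriptions
    containing any non-whitelist drug, and combinations of five or more
    drugs, are discarded.  Each record's price is normalized to 90 days of
    supply, and occurrences are weighted by frequency.
    """
    if n_drugs not in (2, 3, 4):
        raise ValueError("n_drugs must be 2, 3 or 4")
    if not whitelist:
        raise ValueError("whitelist must not be empty")

    groups: dict[tuple[str, datetime.date], list[PrescriptionRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.patient_id, rec.date)].append(rec)

    occurrences: dict[tuple[str, ...], list[float]] = defaultdict(list)
    for recs in groups.values():
        drugs = {r.drug_code for r in recs}
        if len(drugs) != n_drugs or len(drugs) >= 5:
            continue
        if not drugs <= whitelist:
            continue  # combinations including other drugs are excluded
        cost = sum(r.price * 90.0 / r.days_supplied for r in recs)
        occurrences[tuple(sorted(drugs))].append(cost)

    table = pd.DataFrame(
        [{"combination": "+".join(combo), "count": len(costs),
          "mean_cost_3mo": sum(costs) / len(costs)}
         for combo, costs in sorted(occurrences.items())]
    )
    all_costs = [c for costs in occurrences.values() for c in costs]
    mean = sum(all_costs) / len(all_costs) if all_costs else None
    return CombinationCost(n_drugs=n_drugs, mean_cost=mean, frequency_table=table)
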