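"""Synthetic inputs for exercising every stage without external data.

Two generators:

* :func:`generate_prescription_records` emulates a longitudinal
  outpatient prescription extract with a known escalation structure, so
  the claims-based estimators can be validated by parameter recovery:
  each simulated patient starts monotherapy at a random index date after
  a clean washout, escalates through 2-, 3- and 4-drug therapy with the
  given true per-line probabilities at random refill visits inside the
  36-month follow-up, and receives a same-date combination prescription
  every 90 days.  A configurable fraction of noise records (non-whitelist
  drugs and post-follow-up dispensings) is injected.

* :func:`generate_perturbed_scenarios` jitters a base scenario
  multiplicatively (lognormal) into families of valid scenarios for
  property-based testing of the cohort engine.
"""

from __future__ import annotations

import dataclasses
import datetime
from typing import Mapping, Sequence

import numpy as np

from .parameters import CostTable, ParameterSet, PostsurgeryOutcome
from .rwd import PrescriptionRecord

#: Default synthetic ASM whitelist: stand-ins for the eight frequently
#: prescribed drugs plus three recently approved ones (the source extract
#: does not name them).
DEFAULT_WHITELIST = tuple(f"ASM{i:02d}" for i in range(1, 12))

#: Synthetic 90-day prices (JPY) per whitelist drug.
DEFAULT_PRICE_TABLE = {
    drug: 9_000 + 3_000 * i for i, drug in enumerate(DEFAULT_WHITELIST)
}

_REFILL_DAYS = 90
_N_REFILLS = 12  # 12 x 90 d fills the 36-month (1096 d) follow-up


def generate_prescription_records(
    n_patients: int,
    true_probs: Sequence[float] = (0.386, 0.271, 0.235),
    whitelist: Sequence[str] = DEFAULT_WHITELIST,
    price_table: Mapping[str, float] | None = None,
    seed: int = 0,
    noise_fraction: float = 0.05,
    start: datetime.date = datetime.date(2015, 7, 1),
    index_spread_days: int = 1095,
) -> list[PrescriptionRecord]:
    """Simulate dispensing records for ``n_patients`` treatment episodes.

    ``true_probs`` are the per-line escalation probabilities (1->2, 2->3,
    3->4).  Escalations occur at refill visits drawn uniformly so that
    every escalation fits inside the follow-up window; the same-date
    prescription then carries one more whitelist drug.  Records are
    returned sorted and are byte-identical for a fixed ``seed``.
    """
    probs = tuple(float(p) for p in true_probs)
    if len(probs) != 3 or not all(0.0 <= p <= 1.0 for p in probs):
        raise ValueError("true_probs must be three probabilities")
    if price_table is None:
        price_table = DEFAULT_PRICE_TABLE
    whitelist = list(whitelist)
    if len(whitelist) < 4:
        raise ValueError("whitelist must contain at least four drugs")

    rng = np.random.default_rng(seed)
    records: list[PrescriptionRecord] = []

    for i in range(n_patients):
        pid = f"P{i:06d}"
        index = start + datetime.timedelta(
            days=int(rng.integers(0, index_spread_days + 1)))
        drugs = list(rng.choice(whitelist, size=4, replace=False))

        # Refill indices at which each escalation happens; ranges leave
        # room so a 4-drug line is always reachable within follow-up.
        esc_refill = [None, None, None]
        prev = 0
        highs = (_N_REFILLS - 3, _N_REFILLS - 2, _N_REFILLS - 1)
        for k in range(3):
            if rng.random() < probs[k]:
                esc_refill[k] = int(rng.integers(prev + 1, highs[k] + 1))
                prev = esc_refill[k]
            else:
                break

        line = 1
        for refill in range(_N_REFILLS):
            line += sum(1 for k in range(3) if esc_refill[k] == refill)
            date = index + datetime.timedelta(days=refill * _REFILL_DAYS)
            for drug in drugs[:line]:
                records.append(PrescriptionRecord(
                    patient_id=pid, date=date, drug_code=drug,
                    days_supplied=_REFILL_DAYS,
                    price=float(price_table.get(drug, 10_000.0)),
                ))

        # Noise: non-whitelist co-medication inside follow-up, plus an
        # occasional dispensing after the follow-up window.  All random
        # draws happen unconditionally so the stream (and therefore every
        # patient's escalation history) is identical across noise levels.
        u1, off1, code1 = rng.random(), int(rng.integers(0, _N_REFILLS)), \
            int(rng.integers(0, 5))
        u2, off2 = rng.random(), int(rng.integers(0, 70))
        if u1 < noise_fraction:
            records.append(PrescriptionRecord(
                patient_id=pid,
                date=index + datetime.timedelta(days=off1 * _REFILL_DAYS),
                drug_code=f"OTHER{code1:02d}",
                days_supplied=30, price=2_500.0,
            ))
        if u2 < noise_fraction:
            # After the follow-up window but inside the washout distance
            # of the last refill, so it cannot open a second episode.
            records.append(PrescriptionRecord(
                patient_id=pid,
                date=index + datetime.timedelta(days=1097 + off2),
                drug_code=drugs[0], days_supplied=_REFILL_DAYS,
                price=float(price_table.get(drugs[0], 10_000.0)),
            ))

    records.sort(key=lambda r: (r.patient_id, r.date, r.drug_code))
    return records


def records_to_frame(records: Sequence[PrescriptionRecord]):
    """Records as the CSV interchange DataFrame."""
    import pandas as pd

    return pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "date": [r.date.isoformat() for r in records],
        "drug_code": [r.drug_code for r in records],
        "days_supplied": [r.days_supplied for r in records],
        "price_jpy": [r.price for r in records],
    })


# ---------------------------------------------------------------------
# Perturbed scenario families
# ---------------------------------------------------------------------


def _jitter(rng: np.random.Generator, value: float, spread: float,
            upper: float | None = 1.0) -> float:
    out = value * float(rng.lognormal(0.0, spread)) if spread > 0 else value
    if upper is not None:
        out = min(out, upper)
    return max(out, 0.0)


def _jitter_competing(rng, a: float, b: float, spread: float) -> tuple[float, float]:
    """Jitter two competing branch probabilities, rescaling if their sum
    would exceed 1."""
    ja, jb = _jitter(rng, a, spread), _jitter(rng, b, spread)
    total = ja + jb
    if total > 1.0:
        ja, jb = ja / total, jb / total
    return ja, jb


def generate_perturbed_scenarios(
    base: tuple[ParameterSet, CostTable],
    n: int,
    spread: float = 0.1,
    seed: int = 0,
) -> list[tuple[ParameterSet, CostTable]]:
    """``n`` valid scenario copies with multiplicatively jittered scalars.

    Every probability is jittered lognormally with relative SD ``spread``
    and clipped/rescaled so all validation invariants hold by
    construction (competing branch pairs are rescaled onto the simplex;
    outcome probabilities keep freedom <= reduction).
    """
    if spread < 0:
        raise ValueError("spread must be non-negative")
    params, costs = base
    rng = np.random.default_rng(seed)
    out: list[tuple[ParameterSet, CostTable]] = []
    for _ in range(n):
        esc_ns, referral = [], []
        esc_sc, surg = [], []
        for k in range(3):
            r, e = _jitter_competing(rng, params.referral[k], params.esc_ns[k], spread)
            referral.append(r)
            esc_ns.append(e)
            e, s = _jitter_competing(rng, params.esc_sc[k], params.surg_at_transition[k], spread)
            esc_sc.append(e)
            surg.append(s)
        late_surg, red_inflow = _jitter_competing(
            rng, params.late_surgery_annual, params.reduction_inflow_annual, spread)
        outcomes = []
        for o in params.postsurgery_outcome:
            red = _jitter(rng, o.reduction, spread)
            free = min(_jitter(rng, o.freedom, spread), red)
            outcomes.append(PostsurgeryOutcome(freedom=free, reduction=red))
        jittered = dataclasses.replace(
            params,
            esc_ns=tuple(esc_ns),
            esc_sc=tuple(esc_sc),
            referral=tuple(referral),
            surg_at_transition=tuple(surg),
            late_referral_annual=_jitter(rng, params.late_referral_annual, spread),
            late_surgery_annual=late_surg,
            reduction_inflow_annual=red_inflow,
            counter_referral_annual=tuple(
                _jitter(rng, p, spread) for p in params.counter_referral_annual),
            surgery_type_split=tuple(
                _jitter(rng, p, spread) for p in params.surgery_type_split),
            postsurgery_outcome=tuple(outcomes),
        )
        jittered_costs = costs
        if spread > 0:
            for path in costs.scalar_paths():
                jittered_costs = jittered_costs.with_scalar(
                    path, _jitter(rng, costs.get_scalar(path), spread, upper=None))
        out.append((jittered, jittered_costs))
    return out
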