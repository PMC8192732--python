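"""Scenario parameters and cost tables.

A *scenario* is one column of the model's clinical-parameter tables (the
"current" or the "optimized" treatment flow): per-entry escalation and
referral probabilities, surgery diversion probabilities, windowed annual
transition probabilities, surgery-type splits and post-surgical outcome
probabilities, plus the cost tables (age-banded 3-month pharmacotherapy
costs and per-operation surgery costs, both in JPY).

Scenario files are declarative YAML with one shared cost block and one
parameter block per scenario, so both published treatment flows load from
a single bundled file.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from importlib import resources
from typing import Any, Iterator, Mapping

import yaml

logger = logging.getLogger(__name__)

#: Therapy-line transition labels, in order (index 0..2).
LINE_TRANSITIONS = ("1->2", "2->3", "3->4")

PHARMA_BANDS = ("ped_le6", "ped_gt6", "adult")
SURGERY_BANDS = ("le9", "10_14", "15_19", "adult")
NS_COST_ROWS = ("mono", "two", "three", "four")
SC_COST_ROWS = ("mono", "two", "three", "reduction", "difficult")

DEFAULT_LATE_WINDOW_YEARS = 40.0
DEFAULT_COUNTER_WINDOW_YEARS = 5.0
#: Lifetime horizon implied by the published pooled population:
#: 565 077 patients / 7117 incident patients per year = 79.3982 years.
DEFAULT_HORIZON_YEARS = 79.3982


class ValidationError(ValueError):
    """A scenario file or parameter set violates the model's invariants."""


def _as_triple(x: Any, name: str) -> tuple[float, float, float]:
    try:
        vals = tuple(float(v) for v in x)
    except TypeError as exc:
        raise ValidationError(f"{name}: expected three values, got {x!r}") from exc
    if len(vals) != 3:
        raise ValidationError(f"{name}: expected three values, got {len(vals)}")
    return vals  # type: ignore[return-value]


@dataclasses.dataclass(frozen=True)
class PostsurgeryOutcome:
    """Long-term outcome probabilities for one surgery type.

    ``freedom`` is the probability of long-term seizure freedom;
    ``reduction`` the probability of significant seizure reduction among
    patients who do not become seizure free (freedom implies reduction,
    so the validator requires freedom <= reduction as printed).
    """

    freedom: float
    reduction: float


@dataclasses.dataclass(frozen=True)
class ParameterSet:
    """All clinical parameters for one treatment-flow scenario.

    Per-entry probabilities (applied once, at the branch cycle after a
    patient enters a therapy state):

    - ``esc_ns`` / ``esc_sc``: escalation to the next therapy line under
      non-specialized / specialized care, indexed by the transition
      (mono->2, 2->3, 3->4; the specialized 3->4 transition terminates in
      the difficult-to-treat pool).
    - ``referral``: transfer to specialized care at the same line while in
      non-specialized mono-, two-, or three-drug therapy.
    - ``surg_at_transition``: diversion of a specialized-care patient to
      surgery at the transition to the 2-, 3-, or 4-drug line, competing
      with escalation on the same entry mass.

    Windowed annual probabilities:

    - ``late_referral_annual``: NS four-drug -> specialized
      difficult-to-treat, each year within ``late_window_years`` of
      entering the four-drug state.
    - ``late_surgery_annual``: difficult-to-treat -> surgery, same window.
    - ``reduction_inflow_annual``: difficult-to-treat -> seizure-reduction
      pool under specialized care, same window.  Not printed in the
      published parameter tables; bundled scenarios carry a value
      calibrated to reproduce each flow's published annual surgery count.
    - ``counter_referral_annual``: specialized -> non-specialized care at
      the same line, each of the first ``counter_referral_window_years``
      years after settling in a specialized therapy state.
    """

    incident_cohort_size: float
    esc_ns: tuple[float, float, float]
    esc_sc: tuple[float, float, float]
    referral: tuple[float, float, float]
    surg_at_transition: tuple[float, float, float]
    late_referral_annual: float
    late_surgery_annual: float
    counter_referral_annual: tuple[float, float, float]
    surgery_type_split: tuple[float, float, float]  # curative share by line
    postsurgery_outcome: tuple[PostsurgeryOutcome, PostsurgeryOutcome]  # (curative, palliative)
    reduction_inflow_annual: float = 0.0
    late_window_years: float = DEFAULT_LATE_WINDOW_YEARS
    counter_referral_window_years: float = DEFAULT_COUNTER_WINDOW_YEARS
    horizon_years: float = DEFAULT_HORIZON_YEARS

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if not self.incident_cohort_size > 0:
            raise ValidationError("incident_cohort_size must be positive")
        if not self.horizon_years > 0:
            raise ValidationError("horizon_years must be positive")
        for name in ("late_window_years", "counter_referral_window_years"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for name, value in self._probability_items():
            if not 0.0 <= value <= 1.0:
                raise ValidationError(
                    f"{name} = {value!r} is not a probability in [0, 1]"
                )
        for k in range(3):
            ns_sum = self.referral[k] + self.esc_ns[k]
            if ns_sum > 1.0 + 1e-12:
                raise ValidationError(
                    f"competing branches at non-specialized line {k + 1} "
                    f"(referral + escalation = {ns_sum:.6g}) exceed 1"
                )
            sc_sum = self.esc_sc[k] + self.surg_at_transition[k]
            if sc_sum > 1.0 + 1e-12:
                raise ValidationError(
                    f"competing branches at specialized line {k + 1} "
                    f"(escalation + surgery = {sc_sum:.6g}) exceed 1"
                )
        late_sum = self.late_surgery_annual + self.reduction_inflow_annual
        if late_sum > 1.0 + 1e-12:
            raise ValidationError(
                "competing annual outflows from the difficult-to-treat pool "
                f"(surgery + seizure reduction = {late_sum:.6g}) exceed 1"
            )
        for outcome, label in zip(self.postsurgery_outcome, ("curative", "palliative")):
            if outcome.freedom > outcome.reduction + 1e-12:
                raise ValidationError(
                    f"{label} surgery: P(seizure freedom) = {outcome.freedom} exceeds "
                    f"P(significant reduction) = {outcome.reduction}; freedom implies "
                    "reduction"
                )

    def _probability_items(self) -> Iterator[tuple[str, float]]:
        for name in ("esc_ns", "esc_sc", "referral", "surg_at_transition",
                     "counter_referral_annual", "surgery_type_split"):
            for k, v in enumerate(getattr(self, name)):
                yield f"{name}[{k}]", v
        for name in ("late_referral_annual", "late_surgery_annual",
                     "reduction_inflow_annual"):
            yield name, getattr(self, name)
        for label, outcome in zip(("curative", "palliative"), self.postsurgery_outcome):
            yield f"postsurgery_outcome.{label}.freedom", outcome.freedom
            yield f"postsurgery_outcome.{label}.reduction", outcome.reduction

    # -- scalar addressing --------------------------------------------

    def scalar_paths(self, include_durations: bool = False) -> list[str]:
        """Addressable scalar parameter paths (for perturbation audits)."""
        paths = [name for name, _ in self._probability_items()]
        paths.insert(0, "incident_cohort_size")
        if include_durations:
            paths += ["late_window_years", "counter_referral_window_years",
                      "horizon_years"]
        return paths

    def get_scalar(self, path: str) -> float:
        kind, field, index, sub = _parse_path(self, path)
        if kind == "triple":
            return getattr(self, field)[index]
        if kind == "outcome":
            return getattr(getattr(self, field)[index], sub)
        return getattr(self, field)

    def with_scalar(self, path: str, value: float) -> "ParameterSet":
        kind, field, index, sub = _parse_path(self, path)
        if kind == "triple":
            triple = list(getattr(self, field))
            triple[index] = value
            return dataclasses.replace(self, **{field: tuple(triple)})
        if kind == "outcome":
            outcomes = list(self.postsurgery_outcome)
            outcomes[index] = dataclasses.replace(outcomes[index], **{sub: value})
            return dataclasses.replace(self, postsurgery_outcome=tuple(outcomes))
        return dataclasses.replace(self, **{field: value})

    def to_frame(self):
        """Resolved scalar table (parameter, value) for CSV audit export."""
        import pandas as pd

        paths = self.scalar_paths(include_durations=True)
        return pd.DataFrame(
            {"parameter": paths, "value": [self.get_scalar(p) for p in paths]}
        )


_TRIPLE_FIELDS = {"esc_ns", "esc_sc", "referral", "surg_at_transition",
                  "counter_referral_annual", "surgery_type_split"}
_SCALAR_FIELDS = {"incident_cohort_size", "late_referral_annual",
                  "late_surgery_annual", "reduction_inflow_annual",
                  "late_window_years", "counter_referral_window_years",
                  "horizon_years"}
_OUTCOME_TYPES = ("curative", "palliative")


def _parse_path(params: ParameterSet, path: str):
    m = re.fullmatch(r"(\w+)\[(\d)\]", path)
    if m and m.group(1) in _TRIPLE_FIELDS:
        index = int(m.group(2))
        if index > 2:
            raise KeyError(_unknown_path_msg(params, path))
        return "triple", m.group(1), index, None
    m = re.fullmatch(r"postsurgery_outcome\.(curative|palliative)\.(freedom|reduction)",
                     path)
    if m:
        return "outcome", "postsurgery_outcome", _OUTCOME_TYPES.index(m.group(1)), m.group(2)
    if path in _SCALAR_FIELDS:
        return "scalar", path, None, None
    raise KeyError(_unknown_path_msg(params, path))


def _unknown_path_msg(params: ParameterSet, path: str) -> str:
    valid = ", ".join(params.scalar_paths(include_durations=True))
    return f"unknown parameter path {path!r}; valid paths: {valid}"


#: Parameter paths that are probabilities (clipped to [0, 1] on perturbation).
def _is_probability_path(path: str) -> bool:
    return path not in _SCALAR_FIELDS or path in {
        "late_referral_annual", "late_surgery_annual", "reduction_inflow_annual",
    }


def perturb_parameter(params: ParameterSet, name: str, factor: float) -> ParameterSet:
    """Return a copy of ``params`` with one scalar multiplied by ``factor``.

    Probabilities pushed above 1 are clipped to 1 with a logged warning
    (the published sensitivity analysis does not address this case).
    All other fields are unchanged.
    """
    if not factor > 0:
        raise ValueError("factor must be positive")
    value = params.get_scalar(name) * factor
    if _is_probability_path(name) and value > 1.0:
        logger.warning("perturbation of %s to %.6g clipped to 1", name, value)
        value = 1.0
    return params.with_scalar(name, value)


# ---------------------------------------------------------------------
# Cost table
# ---------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CostTable:
    """Age-banded cost parameters in JPY.

    ``pharma_3mo[setting][row][band]`` is the 3-month pharmacotherapy cost
    (including management fees) for a care setting ("non-specialized" or
    "specialized"), state row, and age band (pediatric <= 6 years,
    pediatric > 6 years, adult).  ``surgery[band]`` is the per-operation
    cost for the four surgical age bands (<= 9, 10-14, 15-19, adult).

    ``adult_age_threshold`` is the age (in years) at which the adult
    pharmacotherapy band begins; the published table does not state it,
    and the default of 15 aligns with the surgery table's 15-19 band.
    """

    pharma_3mo: Mapping[str, Mapping[str, Mapping[str, float]]]
    surgery: Mapping[str, float]
    adult_age_threshold: float = 15.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for setting, rows in (("non-specialized", NS_COST_ROWS),
                              ("specialized", SC_COST_ROWS)):
            table = self.pharma_3mo.get(setting)
            if table is None:
                raise ValidationError(f"pharma_3mo missing care setting {setting!r}")
            for row in rows:
                cells = table.get(row)
                if cells is None:
                    raise ValidationError(
                        f"pharma_3mo[{setting}] missing state row {row!r}"
                    )
                for band in PHARMA_BANDS:
                    if band not in cells:
                        raise ValidationError(
                            f"pharma_3mo[{setting}][{row}] missing age band {band!r}"
                        )
                    if cells[band] < 0:
                        raise ValidationError(
                            f"pharma_3mo[{setting}][{row}][{band}] is negative"
                        )
        for band in SURGERY_BANDS:
            if band not in self.surgery:
                raise ValidationError(f"surgery cost missing age band {band!r}")
            if self.surgery[band] < 0:
                raise ValidationError(f"surgery[{band}] is negative")
        if self.adult_age_threshold <= 6:
            raise ValidationError("adult_age_threshold must exceed the pediatric bands")

    def pharma_band(self, age: float) -> str:
        if age <= 6:
            return "ped_le6"
        if age < self.adult_age_threshold:
            return "ped_gt6"
        return "adult"

    def surgery_band(self, age: float) -> str:
        if age <= 9:
            return "le9"
        if age <= 14:
            return "10_14"
        if age <= 19:
            return "15_19"
        return "adult"

    # -- scalar addressing (for sensitivity analysis) ------------------

    def scalar_paths(self) -> list[str]:
        paths = []
        for setting, rows in (("non-specialized", NS_COST_ROWS),
                              ("specialized", SC_COST_ROWS)):
            for row in rows:
                for band in PHARMA_BANDS:
                    paths.append(f"pharma_3mo.{setting}.{row}.{band}")
        paths += [f"surgery.{band}" for band in SURGERY_BANDS]
        return paths

    def get_scalar(self, path: str) -> float:
        parts = path.split(".")
        try:
            if parts[0] == "pharma_3mo" and len(parts) == 4:
                return self.pharma_3mo[parts[1]][parts[2]][parts[3]]
            if parts[0] == "surgery" and len(parts) == 2:
                return self.surgery[parts[1]]
        except KeyError:
            pass
        raise KeyError(
            f"unknown cost path {path!r}; valid paths: {', '.join(self.scalar_paths())}"
        )

    def with_scalar(self, path: str, value: float) -> "CostTable":
        self.get_scalar(path)  # raise on unknown path
        parts = path.split(".")
        if parts[0] == "pharma_3mo":
            pharma = {s: {r: dict(b) for r, b in rows.items()}
                      for s, rows in self.pharma_3mo.items()}
            pharma[parts[1]][parts[2]][parts[3]] = value
            return dataclasses.replace(self, pharma_3mo=pharma)
        surgery = dict(self.surgery)
        surgery[parts[1]] = value
        return dataclasses.replace(self, surgery=surgery)

    def scale(self, factor: float) -> "CostTable":
        """Every cost entry multiplied by ``factor`` (linearity checks)."""
        pharma = {s: {r: {b: v * factor for b, v in bands.items()}
                      for r, bands in rows.items()}
                  for s, rows in self.pharma_3mo.items()}
        surgery = {b: v * factor for b, v in self.surgery.items()}
        return dataclasses.replace(self, pharma_3mo=pharma, surgery=surgery)

    def to_frame(self):
        import pandas as pd

        paths = self.scalar_paths()
        return pd.DataFrame(
            {"parameter": paths, "value": [self.get_scalar(p) for p in paths]}
        )


def perturb_cost(costs: CostTable, name: str, factor: float) -> CostTable:
    if not factor > 0:
        raise ValueError("factor must be positive")
    return costs.with_scalar(name, costs.get_scalar(name) * factor)


# ---------------------------------------------------------------------
# Scenario file I/O
# ---------------------------------------------------------------------


def _params_from_mapping(doc: Mapping[str, Any]) -> ParameterSet:
    required = {"incident_cohort_size", "esc_ns", "esc_sc", "referral",
                "surg_at_transition", "late_referral_annual",
                "late_surgery_annual", "surgery_type_split",
                "postsurgery_outcome"}
    missing = required - set(doc)
    if ("counter_referral_annual" not in doc
            and "counter_referral_window_total" not in doc):
        missing.add("counter_referral_annual")
    if missing:
        raise ValidationError(f"scenario parameters missing fields: {sorted(missing)}")
    outcome_doc = doc["postsurgery_outcome"]
    outcomes = []
    for label in _OUTCOME_TYPES:
        if label not in outcome_doc:
            raise ValidationError(f"postsurgery_outcome missing {label!r}")
        o = outcome_doc[label]
        outcomes.append(PostsurgeryOutcome(freedom=float(o["freedom"]),
                                           reduction=float(o["reduction"])))
    kwargs: dict[str, Any] = dict(
        incident_cohort_size=float(doc["incident_cohort_size"]),
        esc_ns=_as_triple(doc["esc_ns"], "esc_ns"),
        esc_sc=_as_triple(doc["esc_sc"], "esc_sc"),
        referral=_as_triple(doc["referral"], "referral"),
        surg_at_transition=_as_triple(doc["surg_at_transition"], "surg_at_transition"),
        late_referral_annual=float(doc["late_referral_annual"]),
        late_surgery_annual=float(doc["late_surgery_annual"]),
        surgery_type_split=_as_triple(doc["surgery_type_split"], "surgery_type_split"),
        postsurgery_outcome=tuple(outcomes),
    )
    for optional in ("reduction_inflow_annual", "late_window_years",
                     "counter_referral_window_years", "horizon_years"):
        if optional in doc:
            kwargs[optional] = float(doc[optional])
    # Counter-referral may be given either as annual probabilities or as the
    # published cumulative probability over the whole counter-referral
    # window (annual = total / window, a uniform hazard over the window).
    if "counter_referral_annual" in doc:
        kwargs["counter_referral_annual"] = _as_triple(
            doc["counter_referral_annual"], "counter_referral_annual")
    else:
        window = kwargs.get("counter_referral_window_years",
                            DEFAULT_COUNTER_WINDOW_YEARS)
        total = _as_triple(doc["counter_referral_window_total"],
                           "counter_referral_window_total")
        kwargs["counter_referral_annual"] = tuple(p / window for p in total)
    return ParameterSet(**kwargs)


def _params_to_mapping(params: ParameterSet) -> dict[str, Any]:
    return {
        "incident_cohort_size": params.incident_cohort_size,
        "esc_ns": list(params.esc_ns),
        "esc_sc": list(params.esc_sc),
        "referral": list(params.referral),
        "surg_at_transition": list(params.surg_at_transition),
        "late_referral_annual": params.late_referral_annual,
        "late_surgery_annual": params.late_surgery_annual,
        "reduction_inflow_annual": params.reduction_inflow_annual,
        "counter_referral_annual": list(params.counter_referral_annual),
        "surgery_type_split": list(params.surgery_type_split),
        "postsurgery_outcome": {
            label: {"freedom": o.freedom, "reduction": o.reduction}
            for label, o in zip(_OUTCOME_TYPES, params.postsurgery_outcome)
        },
        "late_window_years": params.late_window_years,
        "counter_referral_window_years": params.counter_referral_window_years,
        "horizon_years": params.horizon_years,
    }


def _costs_from_mapping(doc: Mapping[str, Any]) -> CostTable:
    for key in ("pharma_3mo", "surgery"):
        if key not in doc:
            raise ValidationError(f"cost table missing {key!r}")
    kwargs: dict[str, Any] = dict(
        pharma_3mo={s: {r: {b: float(v) for b, v in bands.items()}
                        for r, bands in rows.items()}
                    for s, rows in doc["pharma_3mo"].items()},
        surgery={b: float(v) for b, v in doc["surgery"].items()},
    )
    if "adult_age_threshold" in doc:
        kwargs["adult_age_threshold"] = float(doc["adult_age_threshold"])
    return CostTable(**kwargs)


def _costs_to_mapping(costs: CostTable) -> dict[str, Any]:
    return {
        "pharma_3mo": {s: {r: dict(b) for r, b in rows.items()}
                       for s, rows in costs.pharma_3mo.items()},
        "surgery": dict(costs.surgery),
        "adult_age_threshold": costs.adult_age_threshold,
    }


def load_scenario(path, scenario_name: str) -> tuple[ParameterSet, CostTable]:
    """Load one scenario column from a YAML scenario file.

    The file holds a top-level ``costs`` block (shared across scenarios,
    optionally overridden per scenario) and a ``scenarios`` block with one
    parameter mapping per flow.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return _scenario_from_document(doc, scenario_name, source=str(path))


def _scenario_from_document(doc: Mapping[str, Any], scenario_name: str,
                            source: str) -> tuple[ParameterSet, CostTable]:
    if not isinstance(doc, Mapping) or "scenarios" not in doc:
        raise ValidationError(f"{source}: not a scenario file (no 'scenarios' block)")
    scenarios = doc["scenarios"]
    if scenario_name not in scenarios:
        raise ValidationError(
            f"{source}: no scenario {scenario_name!r}; available: "
            f"{sorted(scenarios)}"
        )
    block = scenarios[scenario_name]
    params = _params_from_mapping(block.get("parameters", block))
    cost_doc = block.get("costs", doc.get("costs"))
    if cost_doc is None:
        raise ValidationError(f"{source}: no cost table for scenario {scenario_name!r}")
    costs = _costs_from_mapping(cost_doc)
    return params, costs


def write_scenario(path, scenarios: Mapping[str, tuple[ParameterSet, CostTable]]) -> None:
    """Write scenarios to a YAML file that round-trips through load_scenario."""
    names = list(scenarios)
    shared_costs = scenarios[names[0]][1]
    doc: dict[str, Any] = {"costs": _costs_to_mapping(shared_costs), "scenarios": {}}
    for name in names:
        params, costs = scenarios[name]
        block: dict[str, Any] = {"parameters": _params_to_mapping(params)}
        if costs is not shared_costs and _costs_to_mapping(costs) != doc["costs"]:
            block["costs"] = _costs_to_mapping(costs)
        doc["scenarios"][name] = block
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def bundled_scenario(scenario_name: str) -> tuple[ParameterSet, CostTable]:
    """Load a scenario ("current" or "optimized") bundled with the package."""
    ref = resources.files("epiflow.data").joinpath("scenarios.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _scenario_from_document(doc, scenario_name, source="bundled scenarios.yaml")


def generate_schema() -> dict[str, Any]:
    """JSON-schema document for scenario files (published interface)."""
    prob = {"type": "number", "minimum": 0, "maximum": 1}
    triple = {"type": "array", "items": prob, "minItems": 3, "maxItems": 3}
    outcome = {
        "type": "object",
        "properties": {"freedom": prob, "reduction": prob},
        "required": ["freedom", "reduction"],
    }
    band_costs = {"type": "object",
                  "properties": {b: {"type": "number", "minimum": 0}
                                 for b in PHARMA_BANDS},
                  "required": list(PHARMA_BANDS)}
    return {
        "$schema": "https://json-schema.org/draft/2020-12/schema",
        "title": "epiflow scenario file",
        "type": "object",
        "required": ["scenarios"],
        "properties": {
            "costs": {
                "type": "object",
                "required": ["pharma_3mo", "surgery"],
                "properties": {
                    "pharma_3mo": {
                        "type": "object",
                        "properties": {
                            "non-specialized": {
                                "type": "object",
                                "properties": {r: band_costs for r in NS_COST_ROWS},
                                "required": list(NS_COST_ROWS),
                            },
                            "specialized": {
                                "type": "object",
                                "properties": {r: band_costs for r in SC_COST_ROWS},
                                "required": list(SC_COST_ROWS),
                            },
                        },
                    },
                    "surgery": {
                        "type": "object",
                        "properties": {b: {"type": "number", "minimum": 0}
                                       for b in SURGERY_BANDS},
                        "required": list(SURGERY_BANDS),
                    },
                    "adult_age_threshold": {"type": "number", "exclusiveMinimum": 6},
                },
            },
            "scenarios": {
                "type": "object",
                "additionalProperties": {
                    "type": "object",
                    "required": ["parameters"],
                    "properties": {
                        "parameters": {
                            "type": "object",
                            "required": [
                                "incident_cohort_size", "esc_ns", "esc_sc",
                                "referral", "surg_at_transition",
                                "late_referral_annual", "late_surgery_annual",
                                "counter_referral_annual", "surgery_type_split",
                                "postsurgery_outcome",
                            ],
                            "properties": {
                                "incident_cohort_size": {"type": "number",
                                                         "exclusiveMinimum": 0},
                                "esc_ns": triple, "esc_sc": triple,
                                "referral": triple, "surg_at_transition": triple,
                                "late_referral_annual": prob,
                                "late_surgery_annual": prob,
                                "reduction_inflow_annual": prob,
                                "counter_referral_annual": triple,
                                "surgery_type_split": triple,
                                "postsurgery_outcome": {
                                    "type": "object",
                                    "properties": {"curative": outcome,
                                                   "palliative": outcome},
                                    "required": ["curative", "palliative"],
                                },
                                "late_window_years": {"type": "number", "minimum": 0},
                                "counter_referral_window_years": {"type": "number",
                                                                  "minimum": 0},
                                "horizon_years": {"type": "number",
                                                  "exclusiveMinimum": 0},
                            },
                        },
                        "costs": {},
                    },
                },
            },
        },
    }
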