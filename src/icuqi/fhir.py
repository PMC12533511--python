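"""FHIR JSON codec for quality indicators.

Each executable indicator is encoded as one Recommendation PlanDefinition;
each of its population-intervention pairs becomes a RecommendationPlan
PlanDefinition whose population is an EvidenceVariable
(RecommendationEligibilityCriteria, Boolean structure carried by the
characteristic ``exclude`` flag and ``definitionByCombination`` nesting)
and whose frequency-based actions are ActivityDefinition
(RecommendationAction) instances with Timing.  Per-shift actions expand
into three ActivityDefinitions (morning, afternoon, night); continuous
criteria and rates are carried as plan ``goal`` elements.

The emitted JSON follows the resource and element names of the
CPG-on-EBMonFHIR profiles (v1.2.0 canonicals in ``meta.profile``); full
conformance to the external implementation guide is not asserted.
Encoding is deterministic: canonical form is UTF-8, sorted keys, 2-space
indent.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path
from typing import Any, Optional

from .model import (
    ActionSpec,
    Atom,
    CmpOp,
    Coding,
    CombinationMethod,
    Comparator,
    Combo,
    Concept,
    CriterionAtom,
    EvaluationUnit,
    Expr,
    GoalSpec,
    IndicatorType,
    Intervention,
    Not,
    QualityIndicator,
    RateSpec,
    RecommendationPlanDef,
    ShiftWindow,
    TimingKind,
    TimingSpec,
)
from .terminology import SYSTEM_URLS, URL_SYSTEMS

PROFILE_BASE = (
    "https://www.netzwerk-universitaetsmedizin.de/fhir/cpg-on-ebm-on-fhir/"
    "StructureDefinition/"
)
PROFILE_RECOMMENDATION = PROFILE_BASE + "recommendation"
PROFILE_PLAN = PROFILE_BASE + "recommendation-plan"
PROFILE_ELIGIBILITY = PROFILE_BASE + "recommendation-eligibility-criteria"
PROFILE_ACTION = PROFILE_BASE + "recommendation-action"

EXT_BASE = "https://divi.de/fhir/StructureDefinition/"
EXT_QI_NUMBER = EXT_BASE + "qi-number"
EXT_QI_TYPE = EXT_BASE + "qi-type"
EXT_EVAL_UNIT = EXT_BASE + "evaluation-unit"
EXT_COMBINATION = EXT_BASE + "combination-method"
EXT_ITEM_KINDS = EXT_BASE + "intervention-item-kinds"
EXT_COMPARATOR = EXT_BASE + "value-comparator"
EXT_CONCEPT_KEY = EXT_BASE + "concept-key"
EXT_OMOP_ID = EXT_BASE + "omop-id"
EXT_HISTORY = EXT_BASE + "pre-admission"
EXT_SHIFT = EXT_BASE + "shift-window"
EXT_REL_ADMISSION = EXT_BASE + "relative-to-admission"
EXT_RATE_DENOM = EXT_BASE + "rate-denominator"

SUBID_SYSTEM = "https://divi.de/fhir/qi-sub-id"

_COMBINATION_CODES = {
    CombinationMethod.ALL: "all-of",
    CombinationMethod.ANY: "any-of",
    CombinationMethod.AT_LEAST: "at-least",
    CombinationMethod.EXACTLY: "exactly",
    CombinationMethod.ONE_OR_MORE: "one-or-more",
}
_CODES_COMBINATION = {v: k for k, v in _COMBINATION_CODES.items()}

_SHIFT_WHEN = {"morning": "MORN", "afternoon": "AFT", "night": "NIGHT"}

ALLOWED_RESOURCE_TYPES = {"PlanDefinition", "EvidenceVariable", "ActivityDefinition"}


class EncodingError(ValueError):
    pass


class DecodeError(ValueError):
    pass


class IntegrityError(DecodeError):
    pass


def canonical_json(obj: Any) -> str:
    return json.dumps(obj, indent=2, sort_keys=True, ensure_ascii=False) + "\n"


@dataclass
class ResourceBundle:
    """An ordered collection of FHIR-JSON resources for one indicator."""

    resources: list[dict] = field(default_factory=list)

    def by_ref(self, ref: str) -> Optional[dict]:
        """Resolve a relative reference like ``PlanDefinition/2a-plan-1``."""
        rtype, _, rid = ref.partition("/")
        for r in self.resources:
            if r.get("resourceType") == rtype and r.get("id") == rid:
                return r
        return None

    def of_type(self, resource_type: str) -> list[dict]:
        return [r for r in self.resources if r.get("resourceType") == resource_type]

    def with_profile(self, profile: str) -> list[dict]:
        return [
            r
            for r in self.resources
            if profile in r.get("meta", {}).get("profile", [])
        ]

    def to_json(self) -> str:
        doc = {
            "resourceType": "Bundle",
            "type": "collection",
            "entry": [{"resource": r} for r in self.resources],
        }
        return canonical_json(doc)

    @classmethod
    def from_json(cls, text: str) -> "ResourceBundle":
        doc = json.loads(text)
        if doc.get("resourceType") == "Bundle":
            return cls([e["resource"] for e in doc.get("entry", [])])
        if isinstance(doc, list):
            return cls(doc)
        return cls([doc])

    def write(self, path: Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: Path) -> "ResourceBundle":
        return cls.from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# shared element codecs


def _coding_to_fhir(c: Coding) -> dict:
    out: dict[str, Any] = {
        "system": SYSTEM_URLS[c.system],
        "code": c.code,
        "display": c.display,
    }
    if c.omop_id is not None:
        out["extension"] = [{"url": EXT_OMOP_ID, "valueInteger": c.omop_id}]
    return out


def _coding_from_fhir(d: dict) -> Coding:
    omop = None
    for ext in d.get("extension", []):
        if ext.get("url") == EXT_OMOP_ID:
            omop = ext.get("valueInteger")
    try:
        system = URL_SYSTEMS[d["system"]]
    except KeyError:
        raise DecodeError(f"unknown coding system {d.get('system')!r}") from None
    return Coding(system, d["code"], d.get("display", ""), omop)


def _concept_to_cc(concept: Concept) -> dict:
    return {
        "extension": [{"url": EXT_CONCEPT_KEY, "valueString": concept.key}],
        "coding": [_coding_to_fhir(c) for c in concept.codings],
        "text": concept.display,
    }


def _concept_from_cc(d: dict) -> Concept:
    key = None
    for ext in d.get("extension", []):
        if ext.get("url") == EXT_CONCEPT_KEY:
            key = ext.get("valueString")
    codings = tuple(_coding_from_fhir(c) for c in d.get("coding", []))
    if not codings:
        raise DecodeError("CodeableConcept without coding")
    if key is None:
        key = codings[0].code
    return Concept(key, d.get("text", codings[0].display), codings)


def _comparator_to_ext(cmp: Comparator) -> dict:
    sub: list[dict] = [
        {"url": "op", "valueCode": cmp.op.value},
        {"url": "value", "valueDecimal": cmp.value},
    ]
    if cmp.value_high is not None:
        sub.append({"url": "high", "valueDecimal": cmp.value_high})
    if cmp.unit:
        sub.append({"url": "unit", "valueString": cmp.unit})
    return {"url": EXT_COMPARATOR, "extension": sub}


def _comparator_from_ext(ext: dict) -> Comparator:
    vals: dict[str, Any] = {}
    for sub in ext.get("extension", []):
        vals[sub["url"]] = sub.get("valueCode", sub.get("valueDecimal", sub.get("valueString")))
    try:
        return Comparator(
            op=CmpOp(vals["op"]),
            value=float(vals["value"]),
            value_high=float(vals["high"]) if "high" in vals else None,
            unit=str(vals.get("unit", "")),
        )
    except (KeyError, ValueError) as exc:
        raise DecodeError(f"malformed comparator extension: {exc}") from exc


def _find_ext(container: dict, url: str) -> Optional[dict]:
    for ext in container.get("extension", []):
        if ext.get("url") == url:
            return ext
    return None


# ---------------------------------------------------------------------------
# population <-> EvidenceVariable characteristic


def _expr_to_characteristic(expr: Expr, exclude: bool = False) -> dict:
    if isinstance(expr, Not):
        if isinstance(expr.child, Not):
            raise EncodingError("double negation is not encodable; simplify the expression")
        return _expr_to_characteristic(expr.child, exclude=True)
    char: dict[str, Any] = {"exclude": exclude}
    if isinstance(expr, Atom):
        atom = expr.atom
        char["definitionCodeableConcept"] = _concept_to_cc(atom.concept)
        exts = []
        if atom.comparator is not None:
            exts.append(_comparator_to_ext(atom.comparator))
        if atom.history:
            exts.append({"url": EXT_HISTORY, "valueBoolean": True})
        if exts:
            char["extension"] = exts
        return char
    assert isinstance(expr, Combo)
    combo: dict[str, Any] = {
        "code": _COMBINATION_CODES[expr.method],
        "characteristic": [_expr_to_characteristic(c) for c in expr.children],
    }
    if expr.n is not None:
        combo["threshold"] = expr.n
    char["definitionByCombination"] = combo
    return char


def _characteristic_to_expr(char: dict) -> Expr:
    expr: Expr
    if "definitionByCombination" in char:
        combo = char["definitionByCombination"]
        code = combo.get("code")
        if code not in _CODES_COMBINATION:
            raise DecodeError(f"unknown combination method {code!r}")
        method = _CODES_COMBINATION[code]
        children = tuple(
            _characteristic_to_expr(c) for c in combo.get("characteristic", [])
        )
        expr = Combo(method, children, n=combo.get("threshold"))
    elif "definitionCodeableConcept" in char:
        concept = _concept_from_cc(char["definitionCodeableConcept"])
        cmp_ext = _find_ext(char, EXT_COMPARATOR)
        comparator = _comparator_from_ext(cmp_ext) if cmp_ext else None
        hist_ext = _find_ext(char, EXT_HISTORY)
        history = bool(hist_ext and hist_ext.get("valueBoolean"))
        expr = Atom(CriterionAtom(concept, comparator, history))
    else:
        raise DecodeError("characteristic lacks a definition element")
    if char.get("exclude"):
        expr = Not(expr)
    return expr


# ---------------------------------------------------------------------------
# timing <-> FHIR Timing


def _time_str(t: time) -> str:
    return t.strftime("%H:%M:%S")


def _timing_to_fhir(timing: TimingSpec, shift: Optional[ShiftWindow] = None) -> dict:
    kind = timing.kind
    if kind is TimingKind.PER_DAY:
        return {"repeat": {"frequency": timing.n, "period": 1, "periodUnit": "d"}}
    if kind is TimingKind.PER_WEEK:
        return {"repeat": {"frequency": timing.n, "period": 1, "periodUnit": "wk"}}
    if kind is TimingKind.ONCE_PER_STAY:
        return {"repeat": {"count": timing.n}}
    if kind is TimingKind.WITHIN_HOURS_OF_ADMISSION:
        return {
            "extension": [{"url": EXT_REL_ADMISSION, "valueBoolean": True}],
            "repeat": {"boundsDuration": {"value": timing.hours, "unit": "h"}},
        }
    assert kind is TimingKind.PER_SHIFT and shift is not None
    return {
        "extension": [
            {
                "url": EXT_SHIFT,
                "extension": [
                    {"url": "label", "valueCode": shift.label},
                    {"url": "start", "valueTime": _time_str(shift.start)},
                    {"url": "end", "valueTime": _time_str(shift.end)},
                ],
            }
        ],
        "repeat": {
            "frequency": timing.n,
            "period": 1,
            "periodUnit": "d",
            "when": [_SHIFT_WHEN[shift.label]],
        },
    }


def _shift_from_timing(timing: dict) -> Optional[ShiftWindow]:
    ext = _find_ext(timing, EXT_SHIFT)
    if ext is None:
        return None
    vals = {s["url"]: s.get("valueCode", s.get("valueTime")) for s in ext["extension"]}
    return ShiftWindow(
        vals["label"],
        time.fromisoformat(vals["start"]),
        time.fromisoformat(vals["end"]),
    )


# ---------------------------------------------------------------------------
# encode


def _activity_definition(
    ad_id: str, action: ActionSpec, shift: Optional[ShiftWindow]
) -> dict:
    res: dict[str, Any] = {
        "resourceType": "ActivityDefinition",
        "id": ad_id,
        "meta": {"profile": [PROFILE_ACTION]},
        "status": "active",
        "code": _concept_to_cc(action.concept),
        "timingTiming": _timing_to_fhir(action.timing, shift),
    }
    if action.negated:
        res["doNotPerform"] = True
    return res


def encode_plan(plan: RecommendationPlanDef) -> list[dict]:
    """Encode one population-intervention pair; returns its resources."""
    ev_id = f"{plan.id}-population"
    evidence_variable = {
        "resourceType": "EvidenceVariable",
        "id": ev_id,
        "meta": {"profile": [PROFILE_ELIGIBILITY]},
        "status": "active",
        "characteristic": [_expr_to_characteristic(plan.population)],
    }

    goals: list[dict] = []
    actions: list[dict] = []
    activity_definitions: list[dict] = []
    item_kinds: list[str] = []
    for item in plan.intervention.items:
        if isinstance(item, GoalSpec):
            item_kinds.append("goal")
            goals.append(
                {
                    "id": f"{plan.id}-goal-{len(goals) + 1}",
                    "description": {"text": item.concept.display},
                    "target": [
                        {
                            "measure": _concept_to_cc(item.concept),
                            "extension": [_comparator_to_ext(item.comparator)],
                        }
                    ],
                }
            )
        elif isinstance(item, RateSpec):
            item_kinds.append("rate")
            target: dict[str, Any] = {"measure": _concept_to_cc(item.numerator_concept)}
            if item.threshold is not None:
                target["extension"] = [_comparator_to_ext(item.threshold)]
            goals.append(
                {
                    "id": f"{plan.id}-goal-{len(goals) + 1}",
                    "extension": [
                        {"url": EXT_RATE_DENOM, "valueString": "per-1000-patient-days"}
                    ],
                    "description": {"text": item.numerator_concept.display},
                    "target": [target],
                }
            )
        else:
            assert isinstance(item, ActionSpec)
            item_kinds.append("action")
            ordinal = sum(1 for k in item_kinds if k == "action")
            base_id = f"{plan.id}-action-{ordinal}"
            if item.timing.kind is TimingKind.PER_SHIFT:
                for shift in item.timing.shifts or ():
                    ad = _activity_definition(f"{base_id}-{shift.label}", item, shift)
                    activity_definitions.append(ad)
                    actions.append(
                        {"definitionCanonical": f"ActivityDefinition/{ad['id']}"}
                    )
            else:
                ad = _activity_definition(base_id, item, None)
                activity_definitions.append(ad)
                actions.append({"definitionCanonical": f"ActivityDefinition/{ad['id']}"})

    extensions: list[dict] = [
        {"url": EXT_EVAL_UNIT, "valueCode": plan.evaluation_unit.value},
        {
            "url": EXT_COMBINATION,
            "extension": [
                {"url": "method", "valueCode": plan.intervention.method.value},
                *(
                    [{"url": "n", "valueInteger": plan.intervention.n}]
                    if plan.intervention.n is not None
                    else []
                ),
            ],
        },
        {"url": EXT_ITEM_KINDS, "valueString": ",".join(item_kinds)},
    ]
    plan_res: dict[str, Any] = {
        "resourceType": "PlanDefinition",
        "id": plan.id,
        "meta": {"profile": [PROFILE_PLAN]},
        "status": "active",
        "extension": extensions,
        "subjectCanonical": f"EvidenceVariable/{ev_id}",
    }
    if goals:
        plan_res["goal"] = goals
    if actions:
        plan_res["action"] = actions
    return [plan_res, evidence_variable, *activity_definitions]


def encode_indicator(qi: QualityIndicator) -> ResourceBundle:
    """Encode a process/outcome indicator into a resource bundle."""
    if qi.type is IndicatorType.STRUCTURE:
        raise EncodingError(
            f"indicator {qi.sub_id} is a structure indicator; structure "
            "indicators are excluded from FHIR encoding"
        )
    recommendation = {
        "resourceType": "PlanDefinition",
        "id": f"{qi.sub_id}-recommendation",
        "meta": {"profile": [PROFILE_RECOMMENDATION]},
        "identifier": [{"system": SUBID_SYSTEM, "value": qi.sub_id}],
        "title": qi.title,
        "description": qi.narrative,
        "status": "active",
        "extension": [
            {"url": EXT_QI_NUMBER, "valueInteger": qi.qi_number},
            {"url": EXT_QI_TYPE, "valueCode": qi.type.value},
        ],
        "action": [
            {"definitionCanonical": f"PlanDefinition/{plan.id}"} for plan in qi.plans
        ],
    }
    resources = [recommendation]
    for plan in qi.plans:
        resources.extend(encode_plan(plan))
    return ResourceBundle(resources)


# ---------------------------------------------------------------------------
# decode


def _decode_action_specs(bundle: ResourceBundle, plan_res: dict) -> list[ActionSpec]:
    """Rebuild ActionSpecs from the plan's action list, re-merging shift triplets."""
    specs: list[ActionSpec] = []
    pending_shift: Optional[dict[str, Any]] = None

    def flush() -> None:
        nonlocal pending_shift
        if pending_shift is not None:
            specs.append(
                ActionSpec(
                    concept=pending_shift["concept"],
                    timing=TimingSpec(
                        TimingKind.PER_SHIFT,
                        n=pending_shift["n"],
                        shifts=tuple(pending_shift["shifts"]),
                    ),
                    negated=pending_shift["negated"],
                )
            )
            pending_shift = None

    for action in plan_res.get("action", []):
        ref = action.get("definitionCanonical", "")
        ad = bundle.by_ref(ref)
        if ad is None:
            raise IntegrityError(f"dangling reference {ref!r}")
        concept = _concept_from_cc(ad["code"])
        negated = bool(ad.get("doNotPerform"))
        timing = ad.get("timingTiming", {})
        repeat = timing.get("repeat", {})
        shift = _shift_from_timing(timing)
        if shift is not None:
            base = ad["id"].rsplit("-", 1)[0]
            if pending_shift is not None and pending_shift["base"] != base:
                flush()
            if pending_shift is None:
                pending_shift = {
                    "base": base,
                    "concept": concept,
                    "n": repeat.get("frequency", 1),
                    "negated": negated,
                    "shifts": [],
                }
            pending_shift["shifts"].append(shift)
            continue
        flush()
        if "boundsDuration" in repeat:
            spec_timing = TimingSpec(
                TimingKind.WITHIN_HOURS_OF_ADMISSION,
                hours=float(repeat["boundsDuration"]["value"]),
            )
        elif "count" in repeat:
            spec_timing = TimingSpec(TimingKind.ONCE_PER_STAY, n=repeat["count"])
        elif repeat.get("periodUnit") == "wk":
            spec_timing = TimingSpec(TimingKind.PER_WEEK, n=repeat.get("frequency", 1))
        elif repeat.get("periodUnit") == "d":
            spec_timing = TimingSpec(TimingKind.PER_DAY, n=repeat.get("frequency", 1))
        else:
            raise DecodeError(f"unrecognized timing on {ad['id']}: {timing}")
        specs.append(ActionSpec(concept, spec_timing, negated))
    flush()
    return specs


def _decode_goal(goal: dict):
    target = goal.get("target", [{}])[0]
    concept = _concept_from_cc(target["measure"])
    cmp_ext = _find_ext(target, EXT_COMPARATOR)
    if _find_ext(goal, EXT_RATE_DENOM) is not None:
        threshold = _comparator_from_ext(cmp_ext) if cmp_ext else None
        return RateSpec(concept, threshold)
    if cmp_ext is None:
        raise DecodeError(f"goal {goal.get('id')} lacks a comparator")
    return GoalSpec(concept, _comparator_from_ext(cmp_ext))


def decode_plan(bundle: ResourceBundle, plan_res: dict) -> RecommendationPlanDef:
    ev_ref = plan_res.get("subjectCanonical", "")
    ev = bundle.by_ref(ev_ref)
    if ev is None:
        raise IntegrityError(f"dangling reference {ev_ref!r}")
    chars = ev.get("characteristic", [])
    if len(chars) != 1:
        raise DecodeError(
            f"EvidenceVariable {ev.get('id')} must have exactly one root characteristic"
        )
    population = _characteristic_to_expr(chars[0])

    unit_ext = _find_ext(plan_res, EXT_EVAL_UNIT)
    if unit_ext is None:
        raise DecodeError(f"plan {plan_res.get('id')} lacks evaluation-unit extension")
    unit = EvaluationUnit(unit_ext["valueCode"])

    combo_ext = _find_ext(plan_res, EXT_COMBINATION)
    if combo_ext is None:
        raise DecodeError(f"plan {plan_res.get('id')} lacks combination-method extension")
    combo_vals = {s["url"]: s.get("valueCode", s.get("valueInteger")) for s in combo_ext["extension"]}
    try:
        method = CombinationMethod(combo_vals["method"])
    except (KeyError, ValueError):
        raise DecodeError(
            f"unknown combination method {combo_vals.get('method')!r}"
        ) from None
    n = combo_vals.get("n")
    if method in (CombinationMethod.AT_LEAST, CombinationMethod.EXACTLY) and n is None:
        raise DecodeError(f"combination method {method.value} requires a count")

    kinds_ext = _find_ext(plan_res, EXT_ITEM_KINDS)
    kinds = kinds_ext["valueString"].split(",") if kinds_ext else None

    goal_items = [_decode_goal(g) for g in plan_res.get("goal", [])]
    action_items = _decode_action_specs(bundle, plan_res)
    if kinds is None:
        items = [*goal_items, *action_items]
    else:
        giter, aiter = iter(goal_items), iter(action_items)
        items = [next(aiter) if k == "action" else next(giter) for k in kinds]
    return RecommendationPlanDef(
        id=plan_res["id"],
        population=population,
        intervention=Intervention(method, tuple(items), n=n),
        evaluation_unit=unit,
    )


def decode_bundle(bundle: ResourceBundle) -> QualityIndicator:
    """Reconstruct the indicator model from an encoded bundle."""
    recommendations = bundle.with_profile(PROFILE_RECOMMENDATION)
    if len(recommendations) != 1:
        raise DecodeError(
            f"bundle must contain exactly one Recommendation, found {len(recommendations)}"
        )
    rec = recommendations[0]
    sub_id = None
    for ident in rec.get("identifier", []):
        if ident.get("system") == SUBID_SYSTEM:
            sub_id = ident.get("value")
    if sub_id is None:
        raise DecodeError("Recommendation lacks a sub-id identifier")
    qi_ext = _find_ext(rec, EXT_QI_NUMBER)
    type_ext = _find_ext(rec, EXT_QI_TYPE)
    if qi_ext is None or type_ext is None:
        raise DecodeError(f"Recommendation {rec.get('id')} lacks qi-number/qi-type")

    plans = []
    for action in rec.get("action", []):
        ref = action.get("definitionCanonical", "")
        plan_res = bundle.by_ref(ref)
        if plan_res is None:
            raise IntegrityError(f"dangling reference {ref!r}")
        plans.append(decode_plan(bundle, plan_res))
    return QualityIndicator(
        qi_number=qi_ext["valueInteger"],
        sub_id=sub_id,
        title=rec.get("title", ""),
        type=IndicatorType(type_ext["valueCode"]),
        plans=tuple(plans),
        narrative=rec.get("description", ""),
    )


# ---------------------------------------------------------------------------
# validation


def _check_characteristic(char: dict, where: str, violations: list[str]) -> None:
    if "definitionByCombination" in char:
        combo = char["definitionByCombination"]
        code = combo.get("code")
        if code not in _CODES_COMBINATION:
            violations.append(f"{where}: unknown combination code {code!r}")
        elif code in ("at-least", "exactly") and "threshold" not in combo:
            violations.append(f"{where}: combination {code} lacks threshold")
        for i, c in enumerate(combo.get("characteristic", [])):
            _check_characteristic(c, f"{where}.characteristic[{i}]", violations)
    elif "definitionCodeableConcept" not in char:
        violations.append(f"{where}: characteristic lacks a definition element")


def validate_bundle(bundle: ResourceBundle) -> list[str]:
    """Structural checks used by this codec; empty list means pass."""
    violations: list[str] = []
    for i, res in enumerate(bundle.resources):
        rtype = res.get("resourceType")
        where = f"resource[{i}]({rtype}/{res.get('id')})"
        if rtype not in ALLOWED_RESOURCE_TYPES:
            violations.append(f"{where}: resourceType {rtype!r} not allowed")
            continue
        if not res.get("id"):
            violations.append(f"{where}: missing id")
        if not res.get("meta", {}).get("profile"):
            violations.append(f"{where}: missing meta.profile")
        for action in res.get("action", []):
            ref = action.get("definitionCanonical")
            if ref and bundle.by_ref(ref) is None:
                violations.append(f"{where}: unresolved reference {ref!r}")
        ref = res.get("subjectCanonical")
        if ref and bundle.by_ref(ref) is None:
            violations.append(f"{where}: unresolved reference {ref!r}")
        if rtype == "EvidenceVariable":
            for j, char in enumerate(res.get("characteristic", [])):
                _check_characteristic(char, f"{where}.characteristic[{j}]", violations)
        if rtype == "ActivityDefinition" and "code" not in res:
            violations.append(f"{where}: ActivityDefinition lacks code")
    if not bundle.with_profile(PROFILE_RECOMMENDATION):
        violations.append("bundle contains no Recommendation PlanDefinition")
    return violations
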