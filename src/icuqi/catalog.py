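"""Bundled indicator catalog: fixture parsing, lookup, and serialization.

The default catalog ships as YAML fixtures inside the package
(``data/catalog/concepts.yaml`` and ``data/catalog/indicators.yaml``) and
round-trips losslessly through :func:`catalog_to_dict` /
:func:`catalog_from_dict`.
"""
from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import yaml

from .model import (
    ActionSpec,
    Atom,
    Catalog,
    CmpOp,
    Coding,
    CombinationMethod,
    Comparator,
    Combo,
    Concept,
    CriterionAtom,
    DEFAULT_SHIFTS,
    EvaluationUnit,
    Expr,
    GoalSpec,
    IndicatorType,
    Intervention,
    Not,
    QualityIndicator,
    RateSpec,
    RecommendationPlanDef,
    System,
    TimingKind,
    TimingSpec,
    validate_catalog,
)


class CatalogError(ValueError):
    """Raised for malformed catalog fixtures; message carries the path."""


class IndicatorNotFoundError(KeyError):
    def __init__(self, sub_id: str, valid: list[str]) -> None:
        super().__init__(
            f"unknown indicator {sub_id!r}; valid ids: {', '.join(valid)}"
        )
        self.sub_id = sub_id
        self.valid = valid


# ---------------------------------------------------------------------------
# dict -> model


def _comparator_from_dict(d: dict[str, Any]) -> Comparator:
    return Comparator(
        op=CmpOp(d["op"]),
        value=float(d["value"]),
        value_high=float(d["value_high"]) if "value_high" in d else None,
        unit=str(d.get("unit", "")),
    )


def _expr_from_dict(d: dict[str, Any], concepts: dict[str, Concept], where: str) -> Expr:
    if "atom" in d:
        key = d["atom"]
        if key not in concepts:
            raise CatalogError(f"{where}: unknown concept {key!r}")
        cmp = _comparator_from_dict(d["cmp"]) if "cmp" in d else None
        return Atom(CriterionAtom(concepts[key], cmp, bool(d.get("history", False))))
    if "not" in d:
        return Not(_expr_from_dict(d["not"], concepts, where))
    for name, method in (
        ("all", CombinationMethod.ALL),
        ("any", CombinationMethod.ANY),
        ("one_or_more", CombinationMethod.ONE_OR_MORE),
    ):
        if name in d:
            children = tuple(_expr_from_dict(c, concepts, where) for c in d[name])
            return Combo(method, children)
    for name, method in (
        ("at_least", CombinationMethod.AT_LEAST),
        ("exactly", CombinationMethod.EXACTLY),
    ):
        if name in d:
            spec = d[name]
            children = tuple(_expr_from_dict(c, concepts, where) for c in spec["of"])
            return Combo(method, children, n=int(spec["n"]))
    raise CatalogError(f"{where}: unrecognized expression node {sorted(d)}")


def _timing_from_dict(d: dict[str, Any]) -> TimingSpec:
    kind = TimingKind(d["kind"])
    return TimingSpec(
        kind=kind,
        n=int(d.get("n", 1)),
        hours=float(d["hours"]) if "hours" in d else None,
        shifts=DEFAULT_SHIFTS if kind is TimingKind.PER_SHIFT else None,
    )


def _item_from_dict(d: dict[str, Any], concepts: dict[str, Concept], where: str):
    if "action" in d:
        a = d["action"]
        return ActionSpec(
            concept=concepts[a["concept"]],
            timing=_timing_from_dict(a["timing"]),
            negated=bool(a.get("negated", False)),
        )
    if "goal" in d:
        g = d["goal"]
        return GoalSpec(concept=concepts[g["concept"]], comparator=_comparator_from_dict(g["cmp"]))
    if "rate" in d:
        r = d["rate"]
        threshold = _comparator_from_dict(r["threshold"]) if "threshold" in r else None
        return RateSpec(numerator_concept=concepts[r["concept"]], threshold=threshold)
    raise CatalogError(f"{where}: unrecognized intervention item {sorted(d)}")


def _intervention_from_dict(
    d: dict[str, Any], concepts: dict[str, Concept], where: str
) -> Intervention:
    return Intervention(
        method=CombinationMethod(d["method"]),
        items=tuple(_item_from_dict(i, concepts, where) for i in d["items"]),
        n=int(d["n"]) if "n" in d else None,
    )


def catalog_from_dict(doc: dict[str, Any]) -> Catalog:
    try:
        concepts: dict[str, Concept] = {}
        for cd in doc.get("concepts", []):
            codings = tuple(
                Coding(
                    system=System(c["system"]),
                    code=str(c["code"]),
                    display=str(c["display"]),
                    omop_id=int(c["omop_id"]) if c.get("omop_id") is not None else None,
                )
                for c in cd["codings"]
            )
            concepts[cd["key"]] = Concept(cd["key"], cd["display"], codings)

        indicators = []
        for idx, qd in enumerate(doc.get("indicators", [])):
            where = f"indicators[{idx}] ({qd.get('sub_id', '?')})"
            plans = tuple(
                RecommendationPlanDef(
                    id=pd["id"],
                    population=_expr_from_dict(pd["population"], concepts, where),
                    intervention=_intervention_from_dict(pd["intervention"], concepts, where),
                    evaluation_unit=EvaluationUnit(pd["evaluation_unit"]),
                )
                for pd in qd.get("plans", [])
            )
            indicators.append(
                QualityIndicator(
                    qi_number=int(qd["qi"]),
                    sub_id=str(qd["sub_id"]),
                    title=str(qd["title"]),
                    type=IndicatorType(qd["type"]),
                    plans=plans,
                    narrative=str(qd.get("narrative", "")).strip(),
                )
            )
        return Catalog(indicators=tuple(indicators), concepts=tuple(concepts.values()))
    except CatalogError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise CatalogError(f"malformed catalog fixture: {exc}") from exc


# ---------------------------------------------------------------------------
# model -> dict


def _comparator_to_dict(c: Comparator) -> dict[str, Any]:
    d: dict[str, Any] = {"op": c.op.value, "value": c.value}
    if c.value_high is not None:
        d["value_high"] = c.value_high
    if c.unit:
        d["unit"] = c.unit
    return d


def _expr_to_dict(e: Expr) -> dict[str, Any]:
    if isinstance(e, Atom):
        d: dict[str, Any] = {"atom": e.atom.concept.key}
        if e.atom.comparator is not None:
            d["cmp"] = _comparator_to_dict(e.atom.comparator)
        if e.atom.history:
            d["history"] = True
        return d
    if isinstance(e, Not):
        return {"not": _expr_to_dict(e.child)}
    assert isinstance(e, Combo)
    children = [_expr_to_dict(c) for c in e.children]
    if e.method in (CombinationMethod.AT_LEAST, CombinationMethod.EXACTLY):
        return {e.method.value.lower(): {"n": e.n, "of": children}}
    return {e.method.value.lower(): children}


def _timing_to_dict(t: TimingSpec) -> dict[str, Any]:
    d: dict[str, Any] = {"kind": t.kind.value}
    if t.n != 1:
        d["n"] = t.n
    if t.hours is not None:
        d["hours"] = t.hours
    return d


def _item_to_dict(item) -> dict[str, Any]:
    if isinstance(item, ActionSpec):
        a: dict[str, Any] = {"concept": item.concept.key, "timing": _timing_to_dict(item.timing)}
        if item.negated:
            a["negated"] = True
        return {"action": a}
    if isinstance(item, GoalSpec):
        return {"goal": {"concept": item.concept.key, "cmp": _comparator_to_dict(item.comparator)}}
    assert isinstance(item, RateSpec)
    r: dict[str, Any] = {"concept": item.numerator_concept.key}
    if item.threshold is not None:
        r["threshold"] = _comparator_to_dict(item.threshold)
    return {"rate": r}


def catalog_to_dict(catalog: Catalog) -> dict[str, Any]:
    return {
        "concepts": [
            {
                "key": c.key,
                "display": c.display,
                "codings": [
                    {
                        "system": cd.system.value,
                        "code": cd.code,
                        "display": cd.display,
                        **({"omop_id": cd.omop_id} if cd.omop_id is not None else {}),
                    }
                    for cd in c.codings
                ],
            }
            for c in catalog.concepts
        ],
        "indicators": [
            {
                "qi": qi.qi_number,
                "sub_id": qi.sub_id,
                "title": qi.title,
                "type": qi.type.value,
                "narrative": qi.narrative,
                "plans": [
                    {
                        "id": p.id,
                        "evaluation_unit": p.evaluation_unit.value,
                        "population": _expr_to_dict(p.population),
                        "intervention": {
                            "method": p.intervention.method.value,
                            **({"n": p.intervention.n} if p.intervention.n is not None else {}),
                            "items": [_item_to_dict(i) for i in p.intervention.items],
                        },
                    }
                    for p in qi.plans
                ],
            }
            for qi in catalog.indicators
        ],
    }


# ---------------------------------------------------------------------------
# loading


def load_catalog_files(concepts_path: Path, indicators_path: Path) -> Catalog:
    concepts_doc = yaml.safe_load(Path(concepts_path).read_text())
    indicators_doc = yaml.safe_load(Path(indicators_path).read_text())
    if not isinstance(concepts_doc, dict) or "concepts" not in concepts_doc:
        raise CatalogError(f"{concepts_path}: missing top-level 'concepts' list")
    if not isinstance(indicators_doc, dict) or "indicators" not in indicators_doc:
        raise CatalogError(f"{indicators_path}: missing top-level 'indicators' list")
    return catalog_from_dict({**concepts_doc, **indicators_doc})


def load_default_catalog() -> Catalog:
    """The bundled catalog of 31 subindicators, validated on load."""
    root = resources.files("icuqi").joinpath("data/catalog")
    with resources.as_file(root.joinpath("concepts.yaml")) as cp, resources.as_file(
        root.joinpath("indicators.yaml")
    ) as ip:
        catalog = load_catalog_files(cp, ip)
    violations = validate_catalog(catalog)
    if violations:
        raise CatalogError("bundled catalog invalid: " + "; ".join(violations))
    return catalog


def counts_by_type(catalog: Catalog) -> dict[IndicatorType, int]:
    counts = {t: 0 for t in IndicatorType}
    for qi in catalog.indicators:
        counts[qi.type] += 1
    return counts


def get_indicator(catalog: Catalog, sub_id: str) -> QualityIndicator:
    for qi in catalog.indicators:
        if qi.sub_id == sub_id:
            return qi
    raise IndicatorNotFoundError(sub_id, [qi.sub_id for qi in catalog.indicators])


def executable_indicators(catalog: Catalog) -> list[QualityIndicator]:
    """Process and outcome indicators (those carrying plans)."""
    return [qi for qi in catalog.indicators if qi.type is not IndicatorType.STRUCTURE]


def dump_compiled_catalog(catalog: Catalog, path: Path) -> None:
    """Single-file compiled catalog JSON (canonical form)."""
    Path(path).write_text(
        json.dumps(catalog_to_dict(catalog), indent=2, sort_keys=True, ensure_ascii=False)
        + "\n"
    )


def load_compiled_catalog(path: Path) -> Catalog:
    return catalog_from_dict(json.loads(Path(path).read_text()))
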