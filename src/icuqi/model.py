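"""Core domain types for computable quality indicators.

The model mirrors the population/intervention decomposition of narrative
quality indicators: concepts carry one or more terminology codings,
populations are nested Boolean expressions over concept atoms, and
interventions are combinations of frequency-based actions, continuous
value goals, and per-1000-patient-day rates.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import time
from enum import Enum
from typing import Mapping, Optional, Union


class System(str, Enum):
    """Terminology a coding belongs to."""

    SNOMED = "SNOMED"
    LOINC = "LOINC"
    DIVI_QI_S = "DIVI_QI_S"


class CmpOp(str, Enum):
    EQ = "EQ"
    NE = "NE"
    LT = "LT"
    LE = "LE"
    GT = "GT"
    GE = "GE"
    RANGE = "RANGE"


class CombinationMethod(str, Enum):
    ALL = "ALL"
    ANY = "ANY"
    AT_LEAST = "AT_LEAST"
    EXACTLY = "EXACTLY"
    ONE_OR_MORE = "ONE_OR_MORE"  # alias of AT_LEAST 1, kept distinct for fidelity


class IndicatorType(str, Enum):
    PROCESS = "process"
    OUTCOME = "outcome"
    STRUCTURE = "structure"


class EvaluationUnit(str, Enum):
    PATIENT_DAY = "PATIENT_DAY"
    STAY = "STAY"
    COHORT_PERIOD = "COHORT_PERIOD"


class TimingKind(str, Enum):
    PER_DAY = "PER_DAY"
    PER_SHIFT = "PER_SHIFT"
    PER_WEEK = "PER_WEEK"
    WITHIN_HOURS_OF_ADMISSION = "WITHIN_HOURS_OF_ADMISSION"
    ONCE_PER_STAY = "ONCE_PER_STAY"


@dataclass(frozen=True)
class Coding:
    """A single code from one vocabulary, with its display name."""

    system: System
    code: str
    display: str
    omop_id: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("Coding.code must be non-empty")


@dataclass(frozen=True)
class Concept:
    """A medical concept annotated with one or more codings."""

    key: str
    display: str
    codings: tuple[Coding, ...]

    def __post_init__(self) -> None:
        if not self.codings:
            raise ValueError(f"Concept {self.key!r} needs at least one coding")
        seen = set()
        for c in self.codings:
            k = (c.system, c.code)
            if k in seen:
                raise ValueError(f"duplicate coding {k} in concept {self.key!r}")
            seen.add(k)


@dataclass(frozen=True)
class Comparator:
    """Numeric constraint on a value-bearing concept.

    Units are opaque strings compared for exact equality; unit conversion
    is deliberately out of scope.
    """

    op: CmpOp
    value: float
    value_high: Optional[float] = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.op is CmpOp.RANGE:
            if self.value_high is None:
                raise ValueError("RANGE comparator requires value_high")
            if self.value > self.value_high:
                raise ValueError("RANGE comparator requires value <= value_high")
        elif self.value_high is not None:
            raise ValueError("value_high only allowed for RANGE")

    def satisfied_by(self, value: float, unit: Optional[str] = None) -> bool:
        """True iff ``value`` (with matching unit) satisfies the constraint."""
        if (unit or "") != self.unit:
            return False
        if self.op is CmpOp.EQ:
            return value == self.value
        if self.op is CmpOp.NE:
            return value != self.value
        if self.op is CmpOp.LT:
            return value < self.value
        if self.op is CmpOp.LE:
            return value <= self.value
        if self.op is CmpOp.GT:
            return value > self.value
        if self.op is CmpOp.GE:
            return value >= self.value
        assert self.op is CmpOp.RANGE
        return self.value <= value <= self.value_high  # type: ignore[operator]


@dataclass(frozen=True)
class CriterionAtom:
    """One population criterion: a concept, optionally value-constrained.

    ``history`` marks pre-admission criteria (e.g. pre-existing home
    ventilation): matching is restricted to events at or before admission.
    """

    concept: Concept
    comparator: Optional[Comparator] = None
    history: bool = False


class Expr:
    """Base class for nested Boolean population expressions."""

    __slots__ = ()


@dataclass(frozen=True)
class Atom(Expr):
    atom: CriterionAtom


@dataclass(frozen=True)
class Not(Expr):
    child: Expr


@dataclass(frozen=True)
class Combo(Expr):
    method: CombinationMethod
    children: tuple[Expr, ...]
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.children:
            raise ValueError("Combo requires at least one child")
        if self.method in (CombinationMethod.AT_LEAST, CombinationMethod.EXACTLY):
            if self.n is None or self.n < 1:
                raise ValueError(f"{self.method.value} requires n >= 1")
            if self.n > len(self.children):
                raise ValueError(f"{self.method.value} n exceeds number of children")
        elif self.n is not None:
            raise ValueError(f"{self.method.value} must not carry n")


def expr_atoms(expr: Expr) -> list[CriterionAtom]:
    """All atoms of ``expr`` in depth-first order (duplicates preserved)."""
    if isinstance(expr, Atom):
        return [expr.atom]
    if isinstance(expr, Not):
        return expr_atoms(expr.child)
    assert isinstance(expr, Combo)
    out: list[CriterionAtom] = []
    for child in expr.children:
        out.extend(expr_atoms(child))
    return out


def expr_eval(expr: Expr, atom_truth: Mapping[CriterionAtom, bool]) -> bool:
    """Evaluate a Boolean expression under an atom truth assignment.

    ALL is conjunction, ANY disjunction; AT_LEAST n / EXACTLY n /
    ONE_OR_MORE count true children.  Raises ``KeyError`` naming any atom
    without an assignment.
    """
    if isinstance(expr, Atom):
        try:
            return atom_truth[expr.atom]
        except KeyError:
            raise KeyError(
                f"no truth assignment for atom {expr.atom.concept.key!r}"
            ) from None
    if isinstance(expr, Not):
        return not expr_eval(expr.child, atom_truth)
    assert isinstance(expr, Combo)
    results = [expr_eval(c, atom_truth) for c in expr.children]
    n_true = sum(results)
    m = expr.method
    if m is CombinationMethod.ALL:
        return n_true == len(results)
    if m is CombinationMethod.ANY:
        return n_true >= 1
    if m is CombinationMethod.ONE_OR_MORE:
        return n_true >= 1
    if m is CombinationMethod.AT_LEAST:
        return n_true >= expr.n  # type: ignore[operator]
    assert m is CombinationMethod.EXACTLY
    return n_true == expr.n


# default clinical shift windows; night wraps past midnight
@dataclass(frozen=True)
class ShiftWindow:
    label: str  # morning | afternoon | night
    start: time
    end: time


DEFAULT_SHIFTS: tuple[ShiftWindow, ...] = (
    ShiftWindow("morning", time(6, 0), time(14, 0)),
    ShiftWindow("afternoon", time(14, 0), time(22, 0)),
    ShiftWindow("night", time(22, 0), time(6, 0)),  # ends next day
)


@dataclass(frozen=True)
class TimingSpec:
    kind: TimingKind
    n: int = 1
    hours: Optional[float] = None
    shifts: Optional[tuple[ShiftWindow, ...]] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("TimingSpec.n must be >= 1")
        if (self.hours is not None) != (
            self.kind is TimingKind.WITHIN_HOURS_OF_ADMISSION
        ):
            raise ValueError("hours present iff kind is WITHIN_HOURS_OF_ADMISSION")
        if (self.shifts is not None) != (self.kind is TimingKind.PER_SHIFT):
            raise ValueError("shifts present iff kind is PER_SHIFT")


@dataclass(frozen=True)
class ActionSpec:
    """An intervention that must occur (or, if negated, not occur)."""

    concept: Concept
    timing: TimingSpec
    negated: bool = False


@dataclass(frozen=True)
class GoalSpec:
    """A continuously applicable value target."""

    concept: Concept
    comparator: Comparator


@dataclass(frozen=True)
class RateSpec:
    """A per-1000-patient-day rate, optionally with a pass threshold.

    Indicators stated as "low number of ..." carry no printed bound and
    are reported without a pass flag (threshold None).
    """

    numerator_concept: Concept
    threshold: Optional[Comparator] = None
    per: int = 1000

    def __post_init__(self) -> None:
        if self.per != 1000:
            raise ValueError("rates are defined per 1000 patient-days")
        if self.threshold is not None and self.threshold.op not in (
            CmpOp.GE,
            CmpOp.GT,
            CmpOp.LE,
            CmpOp.RANGE,
        ):
            raise ValueError("rate threshold op must be GE, GT, LE or RANGE")


InterventionItem = Union[ActionSpec, GoalSpec, RateSpec]


@dataclass(frozen=True)
class Intervention:
    method: CombinationMethod
    items: tuple[InterventionItem, ...]
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("Intervention requires at least one item")
        if self.method in (CombinationMethod.AT_LEAST, CombinationMethod.EXACTLY):
            if self.n is None or self.n < 1:
                raise ValueError(f"{self.method.value} requires n >= 1")
            if self.n > len(self.items):
                raise ValueError("n exceeds number of items")
        elif self.n is not None:
            raise ValueError(f"{self.method.value} must not carry n")


@dataclass(frozen=True)
class RecommendationPlanDef:
    """One population-intervention pair of an indicator."""

    id: str
    population: Expr
    intervention: Intervention
    evaluation_unit: EvaluationUnit


@dataclass(frozen=True)
class QualityIndicator:
    qi_number: int
    sub_id: str
    title: str
    type: IndicatorType
    plans: tuple[RecommendationPlanDef, ...]
    narrative: str = ""


@dataclass(frozen=True)
class Catalog:
    indicators: tuple[QualityIndicator, ...]
    concepts: tuple[Concept, ...]

    def concept(self, key: str) -> Concept:
        for c in self.concepts:
            if c.key == key:
                return c
        raise KeyError(f"unknown concept key {key!r}")


def _plan_concepts(plan: RecommendationPlanDef) -> list[Concept]:
    out = [a.concept for a in expr_atoms(plan.population)]
    for item in plan.intervention.items:
        if isinstance(item, (ActionSpec, GoalSpec)):
            out.append(item.concept)
        else:
            out.append(item.numerator_concept)
    return out


def indicator_concepts(qi: QualityIndicator) -> list[Concept]:
    out: list[Concept] = []
    for plan in qi.plans:
        out.extend(_plan_concepts(plan))
    return out


def validate_catalog(catalog: Catalog) -> list[str]:
    """Check catalog-level invariants; returns violation descriptions.

    Violations are data, not exceptions: a well-formed object graph never
    makes this raise.
    """
    violations: list[str] = []

    seen_keys: set[str] = set()
    seen_codings: dict[str, set[tuple[System, str]]] = {}
    for concept in catalog.concepts:
        if concept.key in seen_keys:
            violations.append(f"duplicate concept key {concept.key!r}")
        seen_keys.add(concept.key)
        seen_codings[concept.key] = {(c.system, c.code) for c in concept.codings}

    seen_sub_ids: set[str] = set()
    for qi in catalog.indicators:
        if qi.sub_id in seen_sub_ids:
            violations.append(f"duplicate sub_id {qi.sub_id!r}")
        seen_sub_ids.add(qi.sub_id)
        if not 1 <= qi.qi_number <= 10:
            violations.append(f"{qi.sub_id}: qi_number {qi.qi_number} out of range 1-10")
        if (qi.type is IndicatorType.STRUCTURE) != (len(qi.plans) == 0):
            violations.append(
                f"{qi.sub_id}: plans must be empty iff type is structure"
            )
        for plan in qi.plans:
            has_rate = any(isinstance(i, RateSpec) for i in plan.intervention.items)
            if has_rate and plan.evaluation_unit is not EvaluationUnit.COHORT_PERIOD:
                violations.append(
                    f"{qi.sub_id}/{plan.id}: rate plans require COHORT_PERIOD"
                )
            has_within = any(
                isinstance(i, ActionSpec)
                and i.timing.kind is TimingKind.WITHIN_HOURS_OF_ADMISSION
                for i in plan.intervention.items
            )
            if has_within and plan.evaluation_unit is not EvaluationUnit.STAY:
                violations.append(
                    f"{qi.sub_id}/{plan.id}: within-hours plans require STAY unit"
                )
            for concept in _plan_concepts(plan):
                if concept.key not in seen_keys:
                    violations.append(
                        f"{qi.sub_id}/{plan.id}: unknown concept {concept.key!r}"
                    )
                elif {(c.system, c.code) for c in concept.codings} != seen_codings[
                    concept.key
                ]:
                    violations.append(
                        f"{qi.sub_id}/{plan.id}: concept {concept.key!r} codings "
                        "differ from catalog definition"
                    )
    return violations
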