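"""Fulfillment engine: match populations and evaluate interventions
against patient event streams.

Conventions
-----------
* A patient-day is a calendar day overlapping the stay; admission and
  discharge days count as full patient-days (timestamps are site-local
  and timezone-naive).
* Concept matching is exact code equality; sites pre-map local data to
  catalog codes.
* A goal with no measurement on a day is not fulfilled: quality cannot be
  demonstrated without measurement.
* Per-shift requirements apply only to shifts lying fully inside the
  stay; a day with no fully-contained shift leaves the denominator.
"""
from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .catalog import get_indicator
from .model import (
    ActionSpec,
    Catalog,
    Comparator,
    Concept,
    CriterionAtom,
    EvaluationUnit,
    Expr,
    GoalSpec,
    IndicatorType,
    Intervention,
    QualityIndicator,
    RateSpec,
    RecommendationPlanDef,
    ShiftWindow,
    System,
    TimingKind,
    expr_atoms,
    expr_eval,
)

log = logging.getLogger(__name__)

HISTORY_LOOKBACK = timedelta(days=365)


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class Event:
    patient_id: str
    time: datetime
    system: System
    code: str
    value: Optional[float] = None
    unit: Optional[str] = None
    end_time: Optional[datetime] = None

    def __post_init__(self) -> None:
        if self.end_time is not None and self.end_time < self.time:
            raise ValueError("end_time must be >= time")


@dataclass
class PatientRecord:
    patient_id: str
    admission: datetime
    discharge: datetime
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.discharge < self.admission:
            raise ValueError("discharge must be >= admission")

    def days(self) -> list[date]:
        out = []
        d = self.admission.date()
        while d <= self.discharge.date():
            out.append(d)
            d += timedelta(days=1)
        return out


# ---------------------------------------------------------------------------
# event stream I/O (JSON Lines)


def _dt(s: str) -> datetime:
    return datetime.fromisoformat(s)


def read_events_jsonl(path: Path) -> list[PatientRecord]:
    stays: dict[str, PatientRecord] = {}
    pending: dict[str, list[Event]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise EvaluationError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            kind = rec.get("type", "event")
            pid = rec["patient_id"]
            if kind == "stay":
                stays[pid] = PatientRecord(pid, _dt(rec["admission"]), _dt(rec["discharge"]))
            elif kind == "event":
                ev = Event(
                    patient_id=pid,
                    time=_dt(rec["time"]),
                    system=System(rec["system"]),
                    code=str(rec["code"]),
                    value=rec.get("value"),
                    unit=rec.get("unit"),
                    end_time=_dt(rec["end_time"]) if rec.get("end_time") else None,
                )
                pending.setdefault(pid, []).append(ev)
            else:
                raise EvaluationError(f"{path}:{lineno}: unknown record type {kind!r}")
    for pid, events in pending.items():
        if pid not in stays:
            raise EvaluationError(f"events for patient {pid!r} without a stay record")
        stays[pid].events.extend(events)
    return list(stays.values())


def write_events_jsonl(patients: Iterable[PatientRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for p in patients:
            fh.write(
                json.dumps(
                    {
                        "type": "stay",
                        "patient_id": p.patient_id,
                        "admission": p.admission.isoformat(),
                        "discharge": p.discharge.isoformat(),
                    }
                )
                + "\n"
            )
            for ev in p.events:
                rec = {
                    "type": "event",
                    "patient_id": ev.patient_id,
                    "time": ev.time.isoformat(),
                    "system": ev.system.value,
                    "code": ev.code,
                }
                if ev.value is not None:
                    rec["value"] = ev.value
                if ev.unit is not None:
                    rec["unit"] = ev.unit
                if ev.end_time is not None:
                    rec["end_time"] = ev.end_time.isoformat()
                fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# matching primitives


def _concept_codes(concept: Concept) -> frozenset[tuple[System, str]]:
    return frozenset((c.system, c.code) for c in concept.codings)


def _events_of(patient: PatientRecord, concept: Concept) -> list[Event]:
    codes = _concept_codes(concept)
    return [e for e in patient.events if (e.system, e.code) in codes]


def _overlaps_day(event: Event, day: date) -> bool:
    start = event.time.date()
    end = event.end_time.date() if event.end_time is not None else start
    return start <= day <= end


def _overlaps_window(event: Event, start: datetime, end: datetime) -> bool:
    ev_end = event.end_time if event.end_time is not None else event.time
    return event.time < end and ev_end >= start


def _satisfies(event: Event, comparator: Comparator) -> Optional[bool]:
    """None when the event carries no value (ignored, logged)."""
    if event.value is None:
        log.debug("event %s/%s lacks a value; ignored", event.system.value, event.code)
        return None
    return comparator.satisfied_by(event.value, event.unit)


def atom_matches(patient: PatientRecord, atom: CriterionAtom, day: Optional[date]) -> bool:
    """True iff an event of the atom's concept overlaps ``day`` (whole stay
    when ``day`` is None) and satisfies the comparator, if any.

    History atoms match only events at or before admission (within a
    one-year lookback).
    """
    events = _events_of(patient, atom.concept)
    if atom.history:
        events = [
            e
            for e in events
            if patient.admission - HISTORY_LOOKBACK <= e.time <= patient.admission
        ]
    elif day is not None:
        events = [e for e in events if _overlaps_day(e, day)]
    else:
        events = [
            e for e in events if _overlaps_window(e, patient.admission, patient.discharge + timedelta(seconds=1))
        ]
    if atom.comparator is None:
        return bool(events)
    return any(_satisfies(e, atom.comparator) for e in events)


def population_matches(patient: PatientRecord, population: Expr, day: Optional[date]) -> bool:
    truth = {atom: atom_matches(patient, atom, day) for atom in expr_atoms(population)}
    return expr_eval(population, truth)


# ---------------------------------------------------------------------------
# shift helpers


def shift_interval(day: date, shift: ShiftWindow) -> tuple[datetime, datetime]:
    start = datetime.combine(day, shift.start)
    end_day = day + timedelta(days=1) if shift.end <= shift.start else day
    end = datetime.combine(end_day, shift.end)
    return start, end


def _shift_fully_inside(patient: PatientRecord, day: date, shift: ShiftWindow) -> bool:
    start, end = shift_interval(day, shift)
    return start >= patient.admission and end <= patient.discharge


# ---------------------------------------------------------------------------
# intervention item evaluation


def _count_events_on_day(patient: PatientRecord, concept: Concept, day: date) -> int:
    return sum(1 for e in _events_of(patient, concept) if _overlaps_day(e, day))


def _action_fulfilled_day(patient: PatientRecord, action: ActionSpec, day: date) -> bool:
    timing = action.timing
    if timing.kind is TimingKind.PER_DAY:
        count = _count_events_on_day(patient, action.concept, day)
        return count == 0 if action.negated else count >= timing.n
    if timing.kind is TimingKind.PER_SHIFT:
        events = _events_of(patient, action.concept)
        for shift in timing.shifts or ():
            if not _shift_fully_inside(patient, day, shift):
                continue
            start, end = shift_interval(day, shift)
            count = sum(1 for e in events if start <= e.time < end)
            if action.negated:
                if count:
                    return False
            elif count < timing.n:
                return False
        return True
    raise EvaluationError(
        f"timing {timing.kind.value} cannot be evaluated per patient-day"
    )


def _action_fulfilled_stay(patient: PatientRecord, action: ActionSpec) -> bool:
    timing = action.timing
    events = _events_of(patient, action.concept)
    if timing.kind is TimingKind.WITHIN_HOURS_OF_ADMISSION:
        deadline = patient.admission + timedelta(hours=timing.hours or 0)
        count = sum(1 for e in events if patient.admission <= e.time <= deadline)
        return count == 0 if action.negated else count >= timing.n
    if timing.kind is TimingKind.ONCE_PER_STAY:
        count = sum(
            1 for e in events if patient.admission <= e.time <= patient.discharge
        )
        return count == 0 if action.negated else count >= timing.n
    if timing.kind is TimingKind.PER_WEEK:
        # every started 7-day block since admission needs its events
        block_start = patient.admission
        while block_start < patient.discharge:
            block_end = min(block_start + timedelta(days=7), patient.discharge)
            count = sum(1 for e in events if block_start <= e.time < block_end)
            if action.negated:
                if count:
                    return False
            elif count < timing.n:
                return False
            block_start = block_end
        return True
    if timing.kind is TimingKind.PER_DAY:
        for day in patient.days():
            count = _count_events_on_day(patient, action.concept, day)
            if action.negated:
                if count:
                    return False
            elif count < timing.n:
                return False
        return True
    raise EvaluationError(f"timing {timing.kind.value} cannot be evaluated per stay")


def _goal_fulfilled_day(patient: PatientRecord, goal: GoalSpec, day: date) -> bool:
    measured = False
    for event in _events_of(patient, goal.concept):
        if not _overlaps_day(event, day):
            continue
        ok = _satisfies(event, goal.comparator)
        if ok is None:
            continue
        if (event.unit or "") != goal.comparator.unit:
            continue  # wrong-unit measurements are ignored
        measured = True
        if not ok:
            return False
    return measured


def _combine(intervention: Intervention, results: Sequence[bool]) -> bool:
    from .model import CombinationMethod

    n_true = sum(results)
    m = intervention.method
    if m is CombinationMethod.ALL:
        return n_true == len(results)
    if m in (CombinationMethod.ANY, CombinationMethod.ONE_OR_MORE):
        return n_true >= 1
    if m is CombinationMethod.AT_LEAST:
        return n_true >= (intervention.n or 1)
    return n_true == intervention.n


def _intervention_fulfilled_day(
    patient: PatientRecord, intervention: Intervention, day: date
) -> bool:
    results = []
    for item in intervention.items:
        if isinstance(item, ActionSpec):
            results.append(_action_fulfilled_day(patient, item, day))
        elif isinstance(item, GoalSpec):
            results.append(_goal_fulfilled_day(patient, item, day))
        else:
            raise EvaluationError("rate items require a COHORT_PERIOD plan")
    return _combine(intervention, results)


def _intervention_fulfilled_stay(patient: PatientRecord, intervention: Intervention) -> bool:
    results = []
    for item in intervention.items:
        if isinstance(item, ActionSpec):
            results.append(_action_fulfilled_stay(patient, item))
        elif isinstance(item, GoalSpec):
            results.append(
                all(_goal_fulfilled_day(patient, item, day) for day in patient.days())
            )
        else:
            raise EvaluationError("rate items require a COHORT_PERIOD plan")
    return _combine(intervention, results)


# ---------------------------------------------------------------------------
# plan evaluation


@dataclass
class PlanRow:
    sub_id: str
    plan_id: str
    unit: str
    denominator: int
    numerator: float
    fraction: Optional[float]
    rate: Optional[float] = None
    threshold: Optional[str] = None
    passed: Optional[bool] = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "sub_id": self.sub_id,
            "plan_id": self.plan_id,
            "unit": self.unit,
            "denominator": self.denominator,
            "numerator": self.numerator,
            "fraction": self.fraction,
            "rate": self.rate,
            "threshold": self.threshold,
            "passed": self.passed,
            "note": self.note,
        }


@dataclass
class FulfillmentReport:
    period_start: date
    period_end: date
    rows: list[PlanRow] = field(default_factory=list)

    def row(self, sub_id: str, plan_id: Optional[str] = None) -> PlanRow:
        for r in self.rows:
            if r.sub_id == sub_id and (plan_id is None or r.plan_id == plan_id):
                return r
        raise KeyError(f"no report row for {sub_id}/{plan_id}")

    def to_dict(self) -> dict:
        return {
            "period": {
                "start": self.period_start.isoformat(),
                "end": self.period_end.isoformat(),
            },
            "rows": [r.to_dict() for r in self.rows],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_csv(self) -> str:
        buf = io.StringIO()
        fields = [
            "sub_id", "plan_id", "unit", "denominator", "numerator",
            "fraction", "rate", "threshold", "passed", "note",
        ]
        writer = csv.DictWriter(buf, fieldnames=fields)
        writer.writeheader()
        for r in self.rows:
            writer.writerow(r.to_dict())
        return buf.getvalue()


def _period_days(patient: PatientRecord, period: tuple[date, date]) -> list[date]:
    return [d for d in patient.days() if period[0] <= d <= period[1]]


def _rate_measure(
    patients: Sequence[PatientRecord],
    plan: RecommendationPlanDef,
    rate: RateSpec,
    period: tuple[date, date],
) -> tuple[int, float]:
    """(matching patient-days, numerator measure).

    The numerator counts events on matching patient-days; when the
    threshold carries a unit (e.g. liters of disinfectant) the values of
    matching-unit events are summed instead of counted.
    """
    unit = rate.threshold.unit if rate.threshold is not None else ""
    days_total = 0
    measure = 0.0
    for patient in patients:
        events = _events_of(patient, rate.numerator_concept)
        for day in _period_days(patient, period):
            if not population_matches(patient, plan.population, day):
                continue
            days_total += 1
            for event in events:
                if not _overlaps_day(event, day):
                    continue
                if unit:
                    if event.value is not None and (event.unit or "") == unit:
                        measure += event.value
                else:
                    measure += 1
    return days_total, measure


def evaluate_plan(
    patients: Sequence[PatientRecord],
    plan: RecommendationPlanDef,
    period: tuple[date, date],
    sub_id: str = "",
) -> tuple[PlanRow, dict]:
    """Evaluate one plan over a cohort.

    Returns the report row plus a detail mapping (evaluation-unit key ->
    fulfilled flag) used to aggregate indicator-level results.
    """
    detail: dict = {}
    if plan.evaluation_unit is EvaluationUnit.PATIENT_DAY:
        shift_actions = [
            i
            for i in plan.intervention.items
            if isinstance(i, ActionSpec) and i.timing.kind is TimingKind.PER_SHIFT
        ]
        for patient in patients:
            for day in _period_days(patient, period):
                if not population_matches(patient, plan.population, day):
                    continue
                if shift_actions and not any(
                    _shift_fully_inside(patient, day, s)
                    for a in shift_actions
                    for s in (a.timing.shifts or ())
                ):
                    continue  # no observable shift on this day
                detail[(patient.patient_id, day)] = _intervention_fulfilled_day(
                    patient, plan.intervention, day
                )
        denominator = len(detail)
        numerator = sum(detail.values())
        row = PlanRow(
            sub_id=sub_id,
            plan_id=plan.id,
            unit="patient-days",
            denominator=denominator,
            numerator=numerator,
            fraction=numerator / denominator if denominator else None,
        )
        return row, detail

    if plan.evaluation_unit is EvaluationUnit.STAY:
        for patient in patients:
            if not (patient.admission.date() <= period[1] and patient.discharge.date() >= period[0]):
                continue
            if not population_matches(patient, plan.population, None):
                continue
            detail[patient.patient_id] = _intervention_fulfilled_stay(
                patient, plan.intervention
            )
        denominator = len(detail)
        numerator = sum(detail.values())
        row = PlanRow(
            sub_id=sub_id,
            plan_id=plan.id,
            unit="stays",
            denominator=denominator,
            numerator=numerator,
            fraction=numerator / denominator if denominator else None,
        )
        return row, detail

    assert plan.evaluation_unit is EvaluationUnit.COHORT_PERIOD
    rates = [i for i in plan.intervention.items if isinstance(i, RateSpec)]
    if len(rates) != 1 or len(plan.intervention.items) != 1:
        raise EvaluationError(
            f"plan {plan.id}: COHORT_PERIOD plans must contain exactly one rate item"
        )
    rate_spec = rates[0]
    days_total, measure = _rate_measure(patients, plan, rate_spec, period)
    rate = 1000.0 * measure / days_total if days_total else None
    passed = None
    threshold_text = None
    if rate_spec.threshold is not None:
        threshold_text = (
            f"{rate_spec.threshold.op.value} {rate_spec.threshold.value}"
            + (f" {rate_spec.threshold.unit}" if rate_spec.threshold.unit else "")
        )
        if rate is not None:
            passed = rate_spec.threshold.satisfied_by(rate, rate_spec.threshold.unit)
    row = PlanRow(
        sub_id=sub_id,
        plan_id=plan.id,
        unit="patient-days",
        denominator=days_total,
        numerator=measure,
        fraction=None,
        rate=rate,
        threshold=threshold_text,
        passed=passed,
    )
    return row, detail


def cohort_period(patients: Sequence[PatientRecord]) -> tuple[date, date]:
    if not patients:
        today = date.today()
        return today, today
    return (
        min(p.admission.date() for p in patients),
        max(p.discharge.date() for p in patients),
    )


def evaluate_indicator(
    patients: Sequence[PatientRecord],
    qi: QualityIndicator,
    period: tuple[date, date],
) -> list[PlanRow]:
    rows = []
    details = []
    for plan in qi.plans:
        row, detail = evaluate_plan(patients, plan, period, sub_id=qi.sub_id)
        rows.append(row)
        details.append(detail)
    if len(qi.plans) > 1 and all(d for d in details) and details[0]:
        keys = set().union(*details)
        combined = {
            key: all(d.get(key, True) for d in details) for key in keys
        }
        denominator = len(combined)
        numerator = sum(combined.values())
        rows.append(
            PlanRow(
                sub_id=qi.sub_id,
                plan_id="*",
                unit=rows[0].unit,
                denominator=denominator,
                numerator=numerator,
                fraction=numerator / denominator if denominator else None,
                note="all plans fulfilled",
            )
        )
    return rows


def evaluate_catalog(
    patients: Sequence[PatientRecord],
    catalog: Catalog,
    period: Optional[tuple[date, date]] = None,
    selection: Optional[Sequence[str]] = None,
) -> FulfillmentReport:
    """Aggregate fulfillment over selected indicators (default: all
    process/outcome indicators)."""
    if period is None:
        period = cohort_period(patients)
    if selection is None:
        sub_ids = [
            qi.sub_id
            for qi in catalog.indicators
            if qi.type is not IndicatorType.STRUCTURE
        ]
    else:
        sub_ids = list(selection)
    report = FulfillmentReport(period_start=period[0], period_end=period[1])
    for sub_id in sub_ids:
        qi = get_indicator(catalog, sub_id)
        if qi.type is IndicatorType.STRUCTURE:
            log.warning("indicator %s is a structure indicator; skipped", sub_id)
            report.rows.append(
                PlanRow(
                    sub_id=sub_id,
                    plan_id="",
                    unit="",
                    denominator=0,
                    numerator=0,
                    fraction=None,
                    note="skipped: structure indicator",
                )
            )
            continue
        report.rows.extend(evaluate_indicator(patients, qi, period))
    return report
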