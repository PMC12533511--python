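"""Seeded synthetic ICU cohort generator.

Cohorts carry population-defining events (stay episodes, ventilation
intervals, scores, orders) planted at configurable prevalences, and
per-indicator intervention events planted with configurable compliance
probabilities — independently per evaluation unit (day/shift/stay), with
no temporal autocorrelation.  Non-compliant goal values are drawn one
resolution step outside the boundary to exercise comparator edges.

Everything is deterministic given the seed; generated events carry only
codings present in the catalog's terminology registry.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from typing import Optional

import numpy as np
import yaml

from .catalog import get_indicator, load_default_catalog
from .evaluation import (
    Event,
    PatientRecord,
    _shift_fully_inside,
    population_matches,
    shift_interval,
)
from .model import (
    ActionSpec,
    Catalog,
    CmpOp,
    CombinationMethod,
    Comparator,
    Concept,
    EvaluationUnit,
    GoalSpec,
    IndicatorType,
    Intervention,
    RateSpec,
    TimingKind,
)


class SimConfigError(ValueError):
    pass


@dataclass
class StaySpec:
    """Stay-length distribution: fixed `days` or geometric with `mean`."""

    kind: str = "fixed"
    days: int = 10
    mean: float = 7.0

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return self.days
        if self.kind == "geometric":
            return int(rng.geometric(1.0 / self.mean))
        raise SimConfigError(f"unknown stay distribution {self.kind!r}")


DEFAULT_PREVALENCE: dict[str, float] = {
    "ventilated": 0.6,
    "ards": 0.5,  # among ventilated patients
    "invasive_device": 0.7,
    "antibiotics": 0.5,
    "nutrition_risk": 0.5,
    "enteral_contraindication": 0.1,
    "immobilization_order": 0.1,
    "home_ventilation": 0.05,
    "obese": 0.2,
    "clinical_nutrition": 0.6,
}


@dataclass
class SimConfig:
    n_patients: int = 100
    stay: StaySpec = field(default_factory=StaySpec)
    compliance: dict[str, float] = field(default_factory=dict)
    rates: dict[str, float] = field(default_factory=dict)
    prevalence: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    start: date = date(2024, 1, 1)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise SimConfigError("n_patients must be >= 0")
        for name, p in {**self.compliance, **self.prevalence}.items():
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"probability for {name!r} outside [0, 1]")
        for name, r in self.rates.items():
            if r < 0:
                raise SimConfigError(f"rate target for {name!r} must be >= 0")

    def prevalence_of(self, key: str) -> float:
        return self.prevalence.get(key, DEFAULT_PREVALENCE[key])

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        doc = yaml.safe_load(text) or {}
        stay = StaySpec(**doc.get("stay", {}))
        return cls(
            n_patients=int(doc.get("n_patients", 100)),
            stay=stay,
            compliance={str(k): float(v) for k, v in (doc.get("compliance") or {}).items()},
            rates={str(k): float(v) for k, v in (doc.get("rates") or {}).items()},
            prevalence={str(k): float(v) for k, v in (doc.get("prevalence") or {}).items()},
            seed=int(doc.get("seed", 0)),
            start=date.fromisoformat(doc["start"]) if "start" in doc else date(2024, 1, 1),
        )


_SHARED_CODES: dict[int, set] = {}


def _planting_coding(concept: Concept, cat: Catalog):
    """Pick a coding unique to this concept so planted events never leak
    into another concept that shares a code (e.g. "Indication of" is used
    by both the device- and antibiotic-indication concepts)."""
    shared = _SHARED_CODES.get(id(cat))
    if shared is None:
        seen: dict[tuple, int] = {}
        for c in cat.concepts:
            for coding in c.codings:
                seen[(coding.system, coding.code)] = seen.get((coding.system, coding.code), 0) + 1
        shared = {k for k, count in seen.items() if count > 1}
        _SHARED_CODES[id(cat)] = shared
    for coding in concept.codings:
        if (coding.system, coding.code) not in shared:
            return coding
    return concept.codings[0]


# catalog in effect during a generate_cohort run (generation is not reentrant)
_ACTIVE_CAT: list[Catalog] = []


def _event(patient: PatientRecord, concept: Concept, when: datetime, value=None,
           unit=None, end: Optional[datetime] = None) -> None:
    c = _planting_coding(concept, _ACTIVE_CAT[-1])
    patient.events.append(
        Event(patient.patient_id, when, c.system, c.code, value, unit, end)
    )


# ---------------------------------------------------------------------------
# population planting


def _plant_population(
    rng: np.random.Generator, patient: PatientRecord, cat: Catalog, cfg: SimConfig
) -> None:
    adm, dis = patient.admission, patient.discharge
    los_hours = (dis - adm).total_seconds() / 3600.0
    _event(patient, cat.concept("intensive_care_patient"), adm, end=dis)
    _event(patient, cat.concept("icu_admission"), adm, value=round(los_hours, 1),
           unit="h", end=dis)

    ventilated = rng.random() < cfg.prevalence_of("ventilated")
    if ventilated:
        _event(patient, cat.concept("invasive_ventilation"), adm, end=dis)
        if rng.random() < cfg.prevalence_of("ards"):
            _event(patient, cat.concept("ards"), adm, end=dis)
            for day in patient.days():
                _event(
                    patient,
                    cat.concept("oxygenation_index"),
                    datetime.combine(day, time(8, 0)),
                    value=float(np.round(rng.uniform(60, 95), 1)),
                )
    if rng.random() < cfg.prevalence_of("invasive_device"):
        _event(patient, cat.concept("invasive_device"), adm, end=dis)
    if rng.random() < cfg.prevalence_of("antibiotics"):
        _event(patient, cat.concept("antibiotic_therapy"), adm, end=dis)
    if rng.random() < cfg.prevalence_of("nutrition_risk"):
        _event(patient, cat.concept("nutrition_risk"), adm + timedelta(hours=1))
    if rng.random() < cfg.prevalence_of("enteral_contraindication"):
        _event(patient, cat.concept("enteral_contraindication"), adm, end=dis)
    if rng.random() < cfg.prevalence_of("immobilization_order"):
        _event(patient, cat.concept("immobilization_order"), adm, end=dis)
    if rng.random() < cfg.prevalence_of("home_ventilation"):
        # pre-existing dependence, documented before admission
        _event(patient, cat.concept("home_ventilation"), adm - timedelta(days=30))
    obese = rng.random() < cfg.prevalence_of("obese")
    _event(patient, cat.concept("bmi"), adm + timedelta(hours=2),
           value=35.0 if obese else 24.0, unit="kg/m2")
    if rng.random() < cfg.prevalence_of("clinical_nutrition"):
        # starts after the early-nutrition window so it does not interact
        # with within-24h planting
        start = adm + timedelta(hours=30)
        if start < dis:
            _event(patient, cat.concept("clinical_nutrition"), start, end=dis)


# ---------------------------------------------------------------------------
# intervention planting


def _goal_value(cmp: Comparator, compliant: bool) -> float:
    step = 1.0
    if cmp.op is CmpOp.EQ:
        return cmp.value if compliant else cmp.value + step
    if cmp.op is CmpOp.NE:
        return cmp.value + step if compliant else cmp.value
    if cmp.op is CmpOp.LT:
        return cmp.value - step if compliant else cmp.value
    if cmp.op is CmpOp.LE:
        return cmp.value if compliant else cmp.value + step
    if cmp.op is CmpOp.GT:
        return cmp.value + step if compliant else cmp.value
    if cmp.op is CmpOp.GE:
        return cmp.value if compliant else cmp.value - step
    assert cmp.op is CmpOp.RANGE
    return cmp.value if compliant else (cmp.value_high or cmp.value) + step


def _plant_goal_day(patient: PatientRecord, goal: GoalSpec, day: date, satisfied: bool) -> None:
    _event(
        patient,
        goal.concept,
        datetime.combine(day, time(9, 0)),
        value=_goal_value(goal.comparator, satisfied),
        unit=goal.comparator.unit or None,
    )


def _plant_action_day(patient: PatientRecord, action: ActionSpec, day: date, satisfied: bool) -> None:
    timing = action.timing
    if action.negated:
        if not satisfied:
            _event(patient, action.concept, datetime.combine(day, time(11, 0)))
        return
    if not satisfied:
        return
    if timing.kind is TimingKind.PER_DAY:
        for j in range(timing.n):
            _event(patient, action.concept, datetime.combine(day, time(10, j * 5)))
    elif timing.kind is TimingKind.PER_SHIFT:
        for shift in timing.shifts or ():
            if not _shift_fully_inside(patient, day, shift):
                continue
            start, _ = shift_interval(day, shift)
            for j in range(timing.n):
                _event(patient, action.concept, start + timedelta(minutes=60 + j))
    else:
        raise SimConfigError(f"{timing.kind.value} action in a patient-day plan")


def _plant_action_stay(patient: PatientRecord, action: ActionSpec, satisfied: bool) -> None:
    timing = action.timing
    adm, dis = patient.admission, patient.discharge
    if action.negated:
        if not satisfied:
            _event(patient, action.concept, max(adm, dis - timedelta(hours=1)))
        return
    if not satisfied:
        return
    if timing.kind is TimingKind.WITHIN_HOURS_OF_ADMISSION:
        for j in range(timing.n):
            _event(
                patient,
                action.concept,
                adm + timedelta(hours=(timing.hours or 0) / 2, minutes=j),
            )
    elif timing.kind is TimingKind.ONCE_PER_STAY:
        for j in range(timing.n):
            _event(patient, action.concept, adm + timedelta(hours=4, minutes=j))
    elif timing.kind is TimingKind.PER_WEEK:
        # events sit late in each block so they cannot double as
        # within-hours-of-admission events of a sibling indicator
        block_start = adm
        while block_start < dis:
            block_end = min(block_start + timedelta(days=7), dis)
            for j in range(timing.n):
                _event(patient, action.concept, block_end - timedelta(hours=1) + timedelta(minutes=j))
            block_start = block_end
    elif timing.kind is TimingKind.PER_DAY:
        for day in patient.days():
            for j in range(timing.n):
                _event(patient, action.concept, datetime.combine(day, time(10, j * 5)))
    else:
        raise SimConfigError(f"{timing.kind.value} action in a stay plan")


def _item_targets(intervention: Intervention, compliant: bool) -> list[bool]:
    """Which items to satisfy so the combination evaluates to `compliant`."""
    k = len(intervention.items)
    m = intervention.method
    if compliant:
        if m is CombinationMethod.ALL:
            return [True] * k
        if m in (CombinationMethod.ANY, CombinationMethod.ONE_OR_MORE):
            return [i == 0 for i in range(k)]
        n = intervention.n or 1
        return [i < n for i in range(k)]
    return [False] * k


def _plant_intervention_day(
    patient: PatientRecord, intervention: Intervention, day: date, compliant: bool
) -> None:
    for item, satisfied in zip(intervention.items, _item_targets(intervention, compliant)):
        if isinstance(item, ActionSpec):
            _plant_action_day(patient, item, day, satisfied)
        elif isinstance(item, GoalSpec):
            _plant_goal_day(patient, item, day, satisfied)
        else:
            raise SimConfigError("rate items are planted via rate targets, not compliance")


def _plant_intervention_stay(
    patient: PatientRecord, intervention: Intervention, compliant: bool
) -> None:
    for item, satisfied in zip(intervention.items, _item_targets(intervention, compliant)):
        if isinstance(item, ActionSpec):
            _plant_action_stay(patient, item, satisfied)
        elif isinstance(item, GoalSpec):
            if satisfied:
                for day in patient.days():
                    _plant_goal_day(patient, item, day, True)
        else:
            raise SimConfigError("rate items are planted via rate targets, not compliance")


def _plant_rate(
    rng: np.random.Generator,
    patient: PatientRecord,
    plan,
    rate: RateSpec,
    target_per_1000: float,
) -> None:
    """Poisson process with intensity target/1000 per matching patient-day."""
    intensity = target_per_1000 / 1000.0
    unit = rate.threshold.unit if rate.threshold is not None else ""
    for day in patient.days():
        if not population_matches(patient, plan.population, day):
            continue
        k = int(rng.poisson(intensity))
        for _ in range(k):
            minutes = int(rng.integers(0, 24 * 60))
            _event(
                patient,
                rate.numerator_concept,
                datetime.combine(day, time(0, 0)) + timedelta(minutes=minutes),
                value=1.0 if unit else None,
                unit=unit or None,
            )


# ---------------------------------------------------------------------------
# public API


def _check_sub_ids(cfg: SimConfig, catalog: Catalog) -> None:
    for sub_id in sorted({*cfg.compliance, *cfg.rates}):
        try:
            qi = get_indicator(catalog, sub_id)
        except KeyError as exc:
            raise SimConfigError(str(exc)) from exc
        if qi.type is IndicatorType.STRUCTURE:
            raise SimConfigError(f"indicator {sub_id} is a structure indicator")
        has_rate = any(
            isinstance(i, RateSpec) for p in qi.plans for i in p.intervention.items
        )
        if sub_id in cfg.compliance and has_rate:
            raise SimConfigError(
                f"indicator {sub_id} is a rate indicator; use 'rates', not 'compliance'"
            )
        if sub_id in cfg.rates and not has_rate:
            raise SimConfigError(f"indicator {sub_id} carries no rate; use 'compliance'")


def generate_cohort(config: SimConfig, catalog: Optional[Catalog] = None) -> list[PatientRecord]:
    """Generate a cohort with per-indicator compliance/rate targets.

    Compliance is drawn independently per evaluation unit.  Plans are
    planted in sorted sub_id order after all population events, so
    population membership seen at planting time equals what the evaluator
    sees.
    """
    cat = catalog or load_default_catalog()
    _check_sub_ids(config, cat)
    rng = np.random.default_rng(config.seed)
    _ACTIVE_CAT.append(cat)
    try:
        return _generate(config, cat, rng)
    finally:
        _ACTIVE_CAT.pop()


def _generate(config: SimConfig, cat: Catalog, rng: np.random.Generator) -> list[PatientRecord]:
    patients: list[PatientRecord] = []
    for i in range(config.n_patients):
        n_days = max(1, config.stay.sample(rng))
        admission = datetime.combine(config.start, time(0, 0))
        discharge = datetime.combine(
            config.start + timedelta(days=n_days - 1), time(23, 59, 59)
        )
        patient = PatientRecord(f"p{i:04d}", admission, discharge)
        _plant_population(rng, patient, cat, config)
        patients.append(patient)

    for sub_id in sorted(config.compliance):
        p = config.compliance[sub_id]
        qi = get_indicator(cat, sub_id)
        for plan in qi.plans:
            for patient in patients:
                if plan.evaluation_unit is EvaluationUnit.PATIENT_DAY:
                    for day in patient.days():
                        if not population_matches(patient, plan.population, day):
                            continue
                        _plant_intervention_day(
                            patient, plan.intervention, day, bool(rng.random() < p)
                        )
                elif plan.evaluation_unit is EvaluationUnit.STAY:
                    if not population_matches(patient, plan.population, None):
                        continue
                    _plant_intervention_stay(
                        patient, plan.intervention, bool(rng.random() < p)
                    )
                else:
                    raise SimConfigError(
                        f"plan {plan.id} is a cohort rate plan; use 'rates'"
                    )

    for sub_id in sorted(config.rates):
        target = config.rates[sub_id]
        qi = get_indicator(cat, sub_id)
        for plan in qi.plans:
            rate_items = [i for i in plan.intervention.items if isinstance(i, RateSpec)]
            for rate in rate_items:
                for patient in patients:
                    _plant_rate(rng, patient, plan, rate, target)

    for patient in patients:
        patient.events.sort(key=lambda e: (e.time, e.system.value, e.code))
    return patients


def generate_rate_cohort(
    config: SimConfig,
    target_rate_per_1000: float,
    sub_id: str = "6b",
    catalog: Optional[Catalog] = None,
) -> list[PatientRecord]:
    """Cohort whose only intervention events are a Poisson-planted rate
    numerator for ``sub_id`` at the given intensity."""
    if target_rate_per_1000 < 0:
        raise SimConfigError("target rate must be >= 0")
    cfg = SimConfig(
        n_patients=config.n_patients,
        stay=config.stay,
        compliance={},
        rates={sub_id: target_rate_per_1000},
        prevalence=config.prevalence,
        seed=config.seed,
        start=config.start,
    )
    return generate_cohort(cfg, catalog)
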