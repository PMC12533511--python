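"""Fulfillment engine: matching, shift semantics, rates, monotonicity."""
from __future__ import annotations

from datetime import date, datetime, timedelta

import pytest

from icuqi.catalog import get_indicator
from icuqi.evaluation import (
    Event,
    PatientRecord,
    atom_matches,
    cohort_period,
    evaluate_catalog,
    evaluate_plan,
    population_matches,
    read_events_jsonl,
    write_events_jsonl,
)
from icuqi.model import (
    CmpOp,
    Comparator,
    CriterionAtom,
    System,
)

D0 = date(2024, 3, 1)


def _dt(day_offset: int, hour: int, minute: int = 0) -> datetime:
    return datetime.combine(D0 + timedelta(days=day_offset), datetime.min.time()) + timedelta(
        hours=hour, minutes=minute
    )


def _patient(days: int = 5, pid: str = "p1") -> PatientRecord:
    return PatientRecord(pid, _dt(0, 0), _dt(days - 1, 23, 59))


def _ev(patient, concept, day_offset, hour, value=None, unit=None, end=None):
    c = concept.codings[0]
    patient.events.append(
        Event(patient.patient_id, _dt(day_offset, hour), c.system, c.code, value, unit, end)
    )


@pytest.fixture
def concepts(catalog):
    return {c.key: c for c in catalog.concepts}


class TestAtomMatching:
    def test_interval_covers_day(self, concepts):
        p = _patient()
        _ev(p, concepts["invasive_ventilation"], 0, 8, end=_dt(3, 12))
        atom = CriterionAtom(concepts["invasive_ventilation"])
        assert atom_matches(p, atom, D0 + timedelta(days=2))
        assert not atom_matches(p, atom, D0 + timedelta(days=4))

    def test_point_event_same_day_only(self, concepts):
        p = _patient()
        _ev(p, concepts["mobilization"], 1, 10)
        atom = CriterionAtom(concepts["mobilization"])
        assert atom_matches(p, atom, D0 + timedelta(days=1))
        assert not atom_matches(p, atom, D0)

    def test_comparator_threshold(self, concepts):
        p = _patient()
        _ev(p, concepts["oxygenation_index"], 0, 8, value=85)
        atom = CriterionAtom(concepts["oxygenation_index"], Comparator(CmpOp.LT, 100))
        assert atom_matches(p, atom, D0)
        p2 = _patient()
        _ev(p2, concepts["oxygenation_index"], 0, 8, value=150)
        assert not atom_matches(p2, atom, D0)

    def test_wrong_unit_ignored(self, concepts):
        p = _patient()
        _ev(p, concepts["plateau_pressure"], 0, 8, value=25, unit="mmHg")
        atom = CriterionAtom(
            concepts["plateau_pressure"], Comparator(CmpOp.LE, 30, unit="cm H2O")
        )
        assert not atom_matches(p, atom, D0)

    def test_valueless_event_ignored_when_comparator_present(self, concepts):
        p = _patient()
        _ev(p, concepts["oxygenation_index"], 0, 8)  # no value
        atom = CriterionAtom(concepts["oxygenation_index"], Comparator(CmpOp.LT, 100))
        assert not atom_matches(p, atom, D0)

    def test_history_atom_pre_admission_only(self, concepts):
        p = _patient()
        p.events.append(
            Event("p1", p.admission - timedelta(days=10),
                  System.SNOMED, "60631000119109")
        )
        atom = CriterionAtom(concepts["home_ventilation"], history=True)
        assert atom_matches(p, atom, D0)
        p2 = _patient()
        _ev(p2, concepts["home_ventilation"], 2, 10)  # during stay: transfer
        assert not atom_matches(p2, atom, D0 + timedelta(days=2))


class TestPopulationMatching:
    def test_qi9_nonmobilization_order_excludes(self, catalog, concepts):
        plan = get_indicator(catalog, "9b").plans[0]
        p = _patient()
        _ev(p, concepts["intensive_care_patient"], 0, 0, end=_dt(4, 23))
        _ev(p, concepts["immobilization_order"], 0, 0, end=_dt(4, 23))
        assert not population_matches(p, plan.population, D0 + timedelta(days=1))

    def test_qi3_all_atoms_satisfied(self, catalog, concepts):
        plan = get_indicator(catalog, "3a").plans[0]
        p = _patient()
        _ev(p, concepts["intensive_care_patient"], 0, 0, end=_dt(4, 23))
        _ev(p, concepts["ards"], 0, 0, end=_dt(4, 23))
        _ev(p, concepts["invasive_ventilation"], 0, 0, end=_dt(4, 23))
        _ev(p, concepts["oxygenation_index"], 1, 8, value=85)
        assert population_matches(p, plan.population, D0 + timedelta(days=1))
        assert not population_matches(p, plan.population, D0 + timedelta(days=2))


class TestShiftSemantics:
    def _sedation_patient(self, concepts, hours):
        p = _patient(days=3)
        _ev(p, concepts["intensive_care_patient"], 0, 0, end=_dt(2, 23))
        for day, hour in hours:
            _ev(p, concepts["sedation_assessment"], day, hour)
        return p

    def test_three_shifts_fulfil_day(self, catalog, concepts):
        plan = get_indicator(catalog, "2a").plans[0]
        p = self._sedation_patient(concepts, [(1, 7), (1, 15), (1, 23)])
        _, detail = evaluate_plan([p], plan, (D0, D0 + timedelta(days=2)), "2a")
        assert detail[("p1", D0 + timedelta(days=1))] is True

    def test_missing_night_shift_fails_day(self, catalog, concepts):
        plan = get_indicator(catalog, "2a").plans[0]
        p = self._sedation_patient(concepts, [(1, 7), (1, 15)])
        _, detail = evaluate_plan([p], plan, (D0, D0 + timedelta(days=2)), "2a")
        assert detail[("p1", D0 + timedelta(days=1))] is False

    def test_midnight_event_belongs_to_previous_night_shift(self, catalog, concepts):
        plan = get_indicator(catalog, "2a").plans[0]
        # day-1 night shift runs [day1 22:00, day2 06:00): an event at
        # day2 02:00 satisfies day 1 and no shift of day 2
        p = self._sedation_patient(concepts, [(1, 7), (1, 15), (2, 2)])
        _, detail = evaluate_plan([p], plan, (D0, D0 + timedelta(days=2)), "2a")
        assert detail[("p1", D0 + timedelta(days=1))] is True
        assert detail[("p1", D0 + timedelta(days=2))] is False

    def test_first_day_without_full_shift_left_out(self, catalog, concepts):
        plan = get_indicator(catalog, "2a").plans[0]
        p = PatientRecord("p1", _dt(0, 23), _dt(1, 23, 59))  # admitted 23:00
        c = concepts["intensive_care_patient"].codings[0]
        p.events.append(Event("p1", p.admission, c.system, c.code, end_time=p.discharge))
        _, detail = evaluate_plan([p], plan, (D0, D0 + timedelta(days=1)), "2a")
        assert ("p1", D0) not in detail  # no shift fully inside on admission day


class TestGoalEvaluation:
    def test_rass_values_in_and_out_of_range(self, catalog, concepts):
        plan = get_indicator(catalog, "2b").plans[0]
        good = _patient(days=1)
        _ev(good, concepts["intensive_care_patient"], 0, 0, end=_dt(0, 23))
        _ev(good, concepts["rass"], 0, 8, value=0)
        _ev(good, concepts["rass"], 0, 14, value=1)
        bad = _patient(days=1, pid="p2")
        _ev(bad, concepts["intensive_care_patient"], 0, 0, end=_dt(0, 23))
        _ev(bad, concepts["rass"], 0, 8, value=0)
        _ev(bad, concepts["rass"], 0, 14, value=-3)
        row, detail = evaluate_plan([good, bad], plan, (D0, D0), "2b")
        assert detail[("p1", D0)] is True
        assert detail[("p2", D0)] is False
        assert row.fraction == 0.5

    def test_unmeasured_day_not_fulfilled(self, catalog, concepts):
        plan = get_indicator(catalog, "2b").plans[0]
        p = _patient(days=1)
        _ev(p, concepts["intensive_care_patient"], 0, 0, end=_dt(0, 23))
        _, detail = evaluate_plan([p], plan, (D0, D0), "2b")
        assert detail[("p1", D0)] is False


class TestRates:
    def _cohort(self, concepts, n_cultures: int):
        patients = []
        for i in range(10):
            p = _patient(days=10, pid=f"p{i}")
            _ev(p, concepts["intensive_care_patient"], 0, 0, end=_dt(9, 23))
            patients.append(p)
        for j in range(n_cultures):
            _ev(patients[j % 10], concepts["blood_culture"], j % 10, 9)
        return patients

    def test_80_per_1000_passes(self, catalog, concepts):
        plan = get_indicator(catalog, "6b").plans[0]
        row, _ = evaluate_plan(self._cohort(concepts, 8), plan, (D0, D0 + timedelta(days=9)), "6b")
        assert row.denominator == 100
        assert row.rate == 80.0
        assert row.passed is True

    def test_70_per_1000_fails(self, catalog, concepts):
        plan = get_indicator(catalog, "6b").plans[0]
        row, _ = evaluate_plan(self._cohort(concepts, 7), plan, (D0, D0 + timedelta(days=9)), "6b")
        assert row.rate == 70.0
        assert row.passed is False

    def test_rate_invariant_to_orderings(self, catalog, concepts):
        plan = get_indicator(catalog, "6b").plans[0]
        patients = self._cohort(concepts, 8)
        row1, _ = evaluate_plan(patients, plan, (D0, D0 + timedelta(days=9)), "6b")
        for p in patients:
            p.events.reverse()
        row2, _ = evaluate_plan(list(reversed(patients)), plan, (D0, D0 + timedelta(days=9)), "6b")
        assert row1.rate == row2.rate

    def test_unbounded_rate_reports_without_pass(self, catalog, concepts):
        plan = get_indicator(catalog, "5d").plans[0]
        patients = self._cohort(concepts, 0)
        for p in patients:
            _ev(p, concepts["invasive_ventilation"], 0, 0, end=_dt(9, 23))
        _ev(patients[0], concepts["vap"], 3, 9)
        row, _ = evaluate_plan(patients, plan, (D0, D0 + timedelta(days=9)), "5d")
        assert row.rate == 10.0
        assert row.passed is None and row.threshold is None

    def test_volume_rate_sums_values(self, catalog, concepts):
        plan = get_indicator(catalog, "5b").plans[0]
        patients = self._cohort(concepts, 0)
        # 9 L over 100 patient-days -> 90 L / 1000 pd
        for j in range(9):
            _ev(patients[j], concepts["hand_disinfectant_use"], j, 12, value=1.0, unit="L")
        row, _ = evaluate_plan(patients, plan, (D0, D0 + timedelta(days=9)), "5b")
        assert row.rate == 90.0
        assert row.passed is True


class TestStayPlans:
    def test_within_24h_mobilization(self, catalog, concepts):
        plan = get_indicator(catalog, "9a").plans[0]
        early = _patient(days=3)
        _ev(early, concepts["intensive_care_patient"], 0, 0, end=_dt(2, 23))
        _ev(early, concepts["mobilization"], 0, 23)
        late = _patient(days=3, pid="p2")
        _ev(late, concepts["intensive_care_patient"], 0, 0, end=_dt(2, 23))
        _ev(late, concepts["mobilization"], 1, 1)  # 25h after admission
        row, detail = evaluate_plan([early, late], plan, (D0, D0 + timedelta(days=2)), "9a")
        assert detail == {"p1": True, "p2": False}

    def test_per_week_blocks(self, catalog, concepts):
        plan = get_indicator(catalog, "8b").plans[0]
        p = _patient(days=10)
        _ev(p, concepts["intensive_care_patient"], 0, 0, end=_dt(9, 23))
        _ev(p, concepts["icu_admission"], 0, 0, value=239.9, unit="h", end=_dt(9, 23))
        _ev(p, concepts["patient_family_interview"], 2, 10)
        _, detail = evaluate_plan([p], plan, (D0, D0 + timedelta(days=9)), "8b")
        assert detail == {"p1": False}  # second week block has no interview
        _ev(p, concepts["patient_family_interview"], 8, 10)
        _, detail = evaluate_plan([p], plan, (D0, D0 + timedelta(days=9)), "8b")
        assert detail == {"p1": True}

    def test_4b_negated_transfer(self, catalog, concepts):
        plan = get_indicator(catalog, "4b").plans[0]
        ok = _patient(days=3)
        _ev(ok, concepts["intensive_care_patient"], 0, 0, end=_dt(2, 23))
        _ev(ok, concepts["invasive_ventilation"], 0, 0, end=_dt(2, 23))
        transferred = _patient(days=3, pid="p2")
        _ev(transferred, concepts["intensive_care_patient"], 0, 0, end=_dt(2, 23))
        _ev(transferred, concepts["invasive_ventilation"], 0, 0, end=_dt(2, 23))
        _ev(transferred, concepts["home_ventilation"], 2, 20)
        row, detail = evaluate_plan([ok, transferred], plan, (D0, D0 + timedelta(days=2)), "4b")
        assert detail == {"p1": True, "p2": False}


class TestAggregation:
    def test_empty_cohort(self, catalog):
        report = evaluate_catalog([], catalog, period=(D0, D0))
        assert all(r.denominator == 0 for r in report.rows)
        assert all(r.fraction is None for r in report.rows)

    def test_structure_indicator_skipped_with_warning_row(self, catalog):
        report = evaluate_catalog([], catalog, period=(D0, D0), selection=["10a"])
        (row,) = report.rows
        assert "structure" in row.note

    def test_monotonicity_under_patient_removal(self, catalog):
        from icuqi.simulate import SimConfig, StaySpec, generate_cohort

        cfg = SimConfig(
            n_patients=30, stay=StaySpec("fixed", 6),
            compliance={"1a": 0.5, "2a": 0.5, "9b": 0.5}, seed=21,
        )
        cohort = generate_cohort(cfg, catalog)
        full = evaluate_catalog(cohort, catalog, selection=["1a", "2a", "9b"])
        reduced = evaluate_catalog(cohort[:-5], catalog, selection=["1a", "2a", "9b"],
                                   period=(full.period_start, full.period_end))
        for r_full, r_red in zip(full.rows, reduced.rows):
            assert r_red.numerator <= r_full.numerator
            assert r_red.denominator <= r_full.denominator
            assert 0 <= r_red.numerator <= r_red.denominator

    def test_indicator_level_row_requires_all_plans(self, catalog, concepts):
        p = _patient(days=1)
        _ev(p, concepts["intensive_care_patient"], 0, 0, end=_dt(0, 23))
        _ev(p, concepts["rass"], 0, 9, value=0)
        _ev(p, concepts["nrs"], 0, 9, value=2)
        _ev(p, concepts["cam_icu"], 0, 9, value=0)
        # ICDSC missing -> delirium plan unfulfilled -> indicator row 0/1
        report = evaluate_catalog([p], catalog, selection=["2b"])
        assert report.row("2b", "2b-plan-2").fraction == 1.0
        assert report.row("2b", "*").fraction == 0.0


class TestEventIO:
    def test_jsonl_roundtrip(self, catalog, tmp_path, concepts):
        p = _patient(days=2)
        _ev(p, concepts["rass"], 0, 9, value=0.0, unit="")
        _ev(p, concepts["invasive_ventilation"], 0, 0, end=_dt(1, 23))
        path = tmp_path / "events.jsonl"
        write_events_jsonl([p], path)
        (loaded,) = read_events_jsonl(path)
        assert loaded == p

    def test_events_without_stay_rejected(self, tmp_path):
        path = tmp_path / "events.jsonl"
        path.write_text(
            '{"type": "event", "patient_id": "px", "time": "2024-01-01T00:00:00", '
            '"system": "SNOMED", "code": "1"}\n'
        )
        from icuqi.evaluation import EvaluationError

        with pytest.raises(EvaluationError, match="px"):
            read_events_jsonl(path)

    def test_cohort_period(self, concepts):
        a = PatientRecord("a", _dt(0, 5), _dt(3, 10))
        b = PatientRecord("b", _dt(2, 5), _dt(7, 10))
        assert cohort_period([a, b]) == (D0, D0 + timedelta(days=7))
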