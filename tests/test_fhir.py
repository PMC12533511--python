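"""FHIR codec: encode/decode round trips, structure, validation."""
from __future__ import annotations

import copy

import pytest

from icuqi.catalog import executable_indicators, get_indicator
from icuqi.fhir import (
    DecodeError,
    EncodingError,
    IntegrityError,
    PROFILE_ELIGIBILITY,
    PROFILE_PLAN,
    PROFILE_RECOMMENDATION,
    ResourceBundle,
    decode_bundle,
    encode_indicator,
    validate_bundle,
)
from icuqi.model import (
    ActionSpec,
    CombinationMethod,
    Combo,
    TimingKind,
)
from icuqi.terminology import SYSTEM_URLS
from icuqi.model import System


class TestEncode:
    def test_2a_expands_to_9_activity_definitions(self, catalog):
        bundle = encode_indicator(get_indicator(catalog, "2a"))
        assert len(bundle.with_profile(PROFILE_PLAN)) == 3
        assert len(bundle.of_type("ActivityDefinition")) == 9
        # three shifts per assessment, tagged morning/afternoon/night
        ids = {r["id"] for r in bundle.of_type("ActivityDefinition")}
        assert sum(1 for i in ids if i.endswith("-morning")) == 3
        assert sum(1 for i in ids if i.endswith("-night")) == 3

    def test_3a_is_goal_only(self, catalog):
        bundle = encode_indicator(get_indicator(catalog, "3a"))
        (plan,) = bundle.with_profile(PROFILE_PLAN)
        assert len(plan["goal"]) == 1
        assert bundle.of_type("ActivityDefinition") == []

    def test_structure_indicator_rejected(self, catalog):
        with pytest.raises(EncodingError, match="structure"):
            encode_indicator(get_indicator(catalog, "10a"))

    def test_activity_definition_count_formula(self, catalog):
        for qi in executable_indicators(catalog):
            bundle = encode_indicator(qi)
            expected = sum(
                (3 if item.timing.kind is TimingKind.PER_SHIFT else 1)
                for plan in qi.plans
                for item in plan.intervention.items
                if isinstance(item, ActionSpec)
            )
            assert len(bundle.of_type("ActivityDefinition")) == expected

    def test_deterministic_canonical_json(self, catalog):
        qi = get_indicator(catalog, "2a")
        assert encode_indicator(qi).to_json() == encode_indicator(qi).to_json()

    def test_one_recommendation_per_indicator(self, catalog):
        for qi in executable_indicators(catalog):
            bundle = encode_indicator(qi)
            assert len(bundle.with_profile(PROFILE_RECOMMENDATION)) == 1


class TestRoundTrip:
    def test_all_executable_indicators(self, catalog):
        for qi in executable_indicators(catalog):
            bundle = encode_indicator(qi)
            assert decode_bundle(bundle) == qi, qi.sub_id

    def test_json_serialization_roundtrip(self, catalog):
        qi = get_indicator(catalog, "4b")
        text = encode_indicator(qi).to_json()
        assert decode_bundle(ResourceBundle.from_json(text)) == qi


class TestValidateBundle:
    def test_all_encodings_clean(self, catalog):
        for qi in executable_indicators(catalog):
            assert validate_bundle(encode_indicator(qi)) == []

    def test_missing_evidence_variable(self, catalog):
        bundle = encode_indicator(get_indicator(catalog, "3a"))
        bundle.resources = [
            r for r in bundle.resources if r["resourceType"] != "EvidenceVariable"
        ]
        violations = validate_bundle(bundle)
        assert any("unresolved reference" in v for v in violations)

    def test_empty_bundle(self):
        violations = validate_bundle(ResourceBundle([]))
        assert violations == ["bundle contains no Recommendation PlanDefinition"]

    def test_unknown_combination_code(self, catalog):
        bundle = encode_indicator(get_indicator(catalog, "4a"))
        bundle = ResourceBundle(copy.deepcopy(bundle.resources))
        for r in bundle.of_type("EvidenceVariable"):
            r["characteristic"][0]["definitionByCombination"]["code"] = "xor"
        assert any("xor" in v for v in validate_bundle(bundle))

    def test_disallowed_resource_type(self, catalog):
        bundle = encode_indicator(get_indicator(catalog, "3a"))
        bundle.resources.append({"resourceType": "Patient", "id": "x"})
        assert any("Patient" in v for v in validate_bundle(bundle))


class TestDecodeErrors:
    def test_dangling_activity_definition(self, catalog):
        bundle = encode_indicator(get_indicator(catalog, "2a"))
        bundle.resources = [
            r for r in bundle.resources if not r["id"].endswith("-night")
        ]
        with pytest.raises(IntegrityError, match="night"):
            decode_bundle(bundle)

    def test_unknown_combination_method(self, catalog):
        bundle = encode_indicator(get_indicator(catalog, "4a"))
        bundle = ResourceBundle(copy.deepcopy(bundle.resources))
        for r in bundle.of_type("EvidenceVariable"):
            r["characteristic"][0]["definitionByCombination"]["code"] = "xor"
        with pytest.raises(DecodeError, match="xor"):
            decode_bundle(bundle)

    def test_bundle_without_recommendation(self):
        with pytest.raises(DecodeError, match="Recommendation"):
            decode_bundle(ResourceBundle([]))


def _cc(code: str, display: str) -> dict:
    return {
        "coding": [{"system": SYSTEM_URLS[System.SNOMED], "code": code, "display": display}],
        "text": display,
    }


class TestHandBuiltBundle:
    def test_any_of_two_population(self):
        """A bundle built by hand per the documented shape decodes to ANY of 2."""
        from icuqi.fhir import (
            EXT_COMBINATION,
            EXT_EVAL_UNIT,
            EXT_ITEM_KINDS,
            EXT_QI_NUMBER,
            EXT_QI_TYPE,
            SUBID_SYSTEM,
        )

        bundle = ResourceBundle(
            [
                {
                    "resourceType": "PlanDefinition",
                    "id": "x-recommendation",
                    "meta": {"profile": [PROFILE_RECOMMENDATION]},
                    "identifier": [{"system": SUBID_SYSTEM, "value": "9x"}],
                    "title": "hand built",
                    "description": "",
                    "status": "active",
                    "extension": [
                        {"url": EXT_QI_NUMBER, "valueInteger": 9},
                        {"url": EXT_QI_TYPE, "valueCode": "process"},
                    ],
                    "action": [{"definitionCanonical": "PlanDefinition/x-plan"}],
                },
                {
                    "resourceType": "PlanDefinition",
                    "id": "x-plan",
                    "meta": {"profile": [PROFILE_PLAN]},
                    "status": "active",
                    "subjectCanonical": "EvidenceVariable/x-pop",
                    "extension": [
                        {"url": EXT_EVAL_UNIT, "valueCode": "PATIENT_DAY"},
                        {
                            "url": EXT_COMBINATION,
                            "extension": [{"url": "method", "valueCode": "ALL"}],
                        },
                        {"url": EXT_ITEM_KINDS, "valueString": "action"},
                    ],
                    "action": [{"definitionCanonical": "ActivityDefinition/x-act"}],
                },
                {
                    "resourceType": "EvidenceVariable",
                    "id": "x-pop",
                    "meta": {"profile": [PROFILE_ELIGIBILITY]},
                    "status": "active",
                    "characteristic": [
                        {
                            "exclude": False,
                            "definitionByCombination": {
                                "code": "any-of",
                                "characteristic": [
                                    {"exclude": False, "definitionCodeableConcept": _cc("74923002", "Mobilization")},
                                    {"exclude": False, "definitionCodeableConcept": _cc("19923001", "Catheter")},
                                ],
                            },
                        }
                    ],
                },
                {
                    "resourceType": "ActivityDefinition",
                    "id": "x-act",
                    "meta": {"profile": ["p"]},
                    "status": "active",
                    "code": _cc("74923002", "Mobilization"),
                    "timingTiming": {"repeat": {"frequency": 1, "period": 1, "periodUnit": "d"}},
                },
            ]
        )
        qi = decode_bundle(bundle)
        pop = qi.plans[0].population
        assert isinstance(pop, Combo)
        assert pop.method is CombinationMethod.ANY
        assert len(pop.children) == 2
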