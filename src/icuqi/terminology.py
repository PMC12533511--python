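"""Code-system registry and concept mapping statistics.

Houses the vocabulary mappings of the indicator catalog, including the
supplementary DIVI-QI-S code system for concepts not representable in
SNOMED CT or LOINC.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .model import Catalog, Coding, System

SYSTEM_URLS = {
    System.SNOMED: "http://snomed.info/sct",
    System.LOINC: "http://loinc.org",
    System.DIVI_QI_S: "https://divi.de/fhir/CodeSystem/divi-qi-s",
}
URL_SYSTEMS = {v: k for k, v in SYSTEM_URLS.items()}

INTERNATIONAL_SYSTEMS = frozenset({System.SNOMED, System.LOINC})

#: the 6 supplementary codes; the registry refuses any other DIVI-QI-S code
DIVI_QI_S_CODES = frozenset(
    {"FA-ZB-ITS", "TAGESZIEL", "BPS", "CAM-ICU", "ICDSC", "tvpibw"}
)


class CodeNotFoundError(KeyError):
    def __init__(self, system: System, code: str) -> None:
        super().__init__(f"no entry for code {code!r} in system {system.value}")
        self.system = system
        self.code = code


@dataclass(frozen=True)
class CodeSystemEntry:
    system: System
    code: str
    display: str
    omop_id: Optional[int] = None


@dataclass(frozen=True)
class ConceptStats:
    unique_concepts: int
    mapped_international: int
    custom_divi: int
    pct_mapped: int

    def __post_init__(self) -> None:
        assert self.unique_concepts == self.mapped_international + self.custom_divi


class Registry:
    """Lookup table of (system, code) -> entry, one entry per code."""

    def __init__(self, entries: Iterable[CodeSystemEntry] = ()) -> None:
        self._entries: dict[tuple[System, str], CodeSystemEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: CodeSystemEntry) -> None:
        if not entry.display:
            raise ValueError(
                f"entry ({entry.system.value}, {entry.code!r}) lacks a display name"
            )
        if entry.system is System.DIVI_QI_S and entry.code not in DIVI_QI_S_CODES:
            raise ValueError(
                f"unknown DIVI-QI-S code {entry.code!r}; the supplementary system "
                f"defines exactly {sorted(DIVI_QI_S_CODES)}"
            )
        key = (entry.system, entry.code)
        existing = self._entries.get(key)
        if existing is not None and existing != entry:
            raise ValueError(f"conflicting redefinition of {key}")
        self._entries[key] = entry

    def lookup(self, system: System, code: str) -> CodeSystemEntry:
        try:
            return self._entries[(System(system), code)]
        except KeyError:
            raise CodeNotFoundError(System(system), code) from None

    def __contains__(self, key: tuple[System, str]) -> bool:
        return (System(key[0]), key[1]) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def entries(self) -> list[CodeSystemEntry]:
        return sorted(
            self._entries.values(), key=lambda e: (e.system.value, e.code)
        )

    @classmethod
    def from_catalog(cls, catalog: Catalog) -> "Registry":
        reg = cls()
        for concept in catalog.concepts:
            for c in concept.codings:
                reg.add(CodeSystemEntry(c.system, c.code, c.display, c.omop_id))
        return reg

    # -- code-system JSON import/export (one file per system) -------------

    def to_codesystem_json(self, system: System) -> dict:
        return {
            "resourceType": "CodeSystem",
            "url": SYSTEM_URLS[system],
            "version": "2023",
            "content": "fragment",
            "concept": [
                {
                    "code": e.code,
                    "display": e.display,
                    **(
                        {"property": [{"code": "omop-id", "valueInteger": e.omop_id}]}
                        if e.omop_id is not None
                        else {}
                    ),
                }
                for e in self.entries()
                if e.system is system
            ],
        }

    def export_codesystems(self, directory: Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for system in System:
            doc = self.to_codesystem_json(system)
            path = directory / f"codesystem-{system.value.lower().replace('_', '-')}.json"
            path.write_text(
                json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False) + "\n"
            )
            paths.append(path)
        return paths

    @classmethod
    def import_codesystems(cls, paths: Iterable[Path]) -> "Registry":
        reg = cls()
        for path in paths:
            doc = json.loads(Path(path).read_text())
            system = URL_SYSTEMS[doc["url"]]
            for c in doc.get("concept", []):
                omop = None
                for prop in c.get("property", []):
                    if prop.get("code") == "omop-id":
                        omop = prop.get("valueInteger")
                reg.add(CodeSystemEntry(system, c["code"], c["display"], omop))
        return reg


def concept_stats(catalog: Catalog) -> ConceptStats:
    """Mapping statistics at (system, code) granularity.

    A code shared by several indicators counts once; a code counts as
    internationally mapped iff its system is SNOMED CT or LOINC.
    """
    unique: set[tuple[System, str]] = set()
    for concept in catalog.concepts:
        for coding in concept.codings:
            unique.add((coding.system, coding.code))
    mapped = sum(1 for system, _ in unique if system in INTERNATIONAL_SYSTEMS)
    custom = len(unique) - mapped
    pct = round(100 * mapped / len(unique)) if unique else 0
    return ConceptStats(
        unique_concepts=len(unique),
        mapped_international=mapped,
        custom_divi=custom,
        pct_mapped=pct,
    )


def coding_in_registry(coding: Coding, registry: Registry) -> bool:
    return (coding.system, coding.code) in registry
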