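# icuqi

Computer-interpretable ICU quality indicators: a machine-readable catalog
of the DIVI intensive-care quality indicators with terminology mappings,
a FHIR JSON codec, human-readable back-translation, a fulfillment
evaluation engine, and a seeded synthetic cohort generator.

The 10 quality indicators decompose into 31 separately measurable
subindicators (9 structure, 17 process, 5 outcome). The 22 process and
outcome subindicators carry executable population/intervention plans over
58 unique coded medical concepts, 52 of which map to SNOMED CT or LOINC;
the remaining 6 live in the supplementary DIVI-QI-S code system.

## Layout

| Module | Purpose |
|---|---|
| `icuqi.model` | Domain types: concepts, Boolean criteria, timing, goals, rates, indicators |
| `icuqi.terminology` | Code-system registry, lookups, mapping statistics |
| `icuqi.catalog` | Bundled catalog fixtures (`data/catalog/*.yaml`), loaders, serialization |
| `icuqi.fhir` | Encode/decode indicators to CPG-on-EBMonFHIR-shaped PlanDefinition / EvidenceVariable / ActivityDefinition JSON |
| `icuqi.backtranslate` | Render plans into the human-readable intermediate representation and parse it back |
| `icuqi.evaluation` | Fulfillment engine: patient-day / stay / per-1000-patient-day evaluation over JSONL event streams |
| `icuqi.simulate` | Seeded synthetic ICU cohorts with configurable per-indicator compliance |
| `icuqi.cli` | `icuqi` command-line entry point |

## CLI

```sh
icuqi catalog stats                 # 31 indicators, 58 concepts, 52 mapped, 6 custom
icuqi catalog show 3a
icuqi encode --all --out bundles/   # FHIR JSON, one bundle per indicator
icuqi validate --in bundles/
icuqi decode --in bundles/
icuqi backtranslate --id 4a         # intermediate representation
icuqi simulate --config sim.yaml --out events.jsonl
icuqi evaluate --events events.jsonl --ids 2a,3a --out report.json
```

Simulation config (YAML):

```yaml
n_patients: 200
stay: {kind: fixed, days: 10}       # or {kind: geometric, mean: 7}
compliance: {2a: 0.8, 9b: 0.7}      # per-indicator probability per day/shift/stay
rates: {6b: 80}                     # Poisson targets per 1000 patient-days
seed: 1
```

Global flags: `--seed`, `--log-level`, `--format json|csv`.

## Notes

* Events are exchanged as JSON Lines (`{"type": "stay", ...}` /
  `{"type": "event", ...}` records); reports as JSON or CSV.
* Concept matching is exact code equality — sites pre-map local data to
  catalog codes. Units are opaque strings compared exactly.
* A patient-day is a calendar day overlapping the stay; the night shift
  of day *d* is [*d* 22:00, *d*+1 06:00).
* Structure indicators are narrative-only by design and are rejected by
  the FHIR encoder.
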