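{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Patient event stream record (JSON Lines, one object per line)",
  "oneOf": [
    {
      "type": "object",
      "required": ["type", "patient_id", "admission", "discharge"],
      "properties": {
        "type": {"const": "stay"},
        "patient_id": {"type": "string"},
        "admission": {"type": "string", "format": "date-time"},
        "discharge": {"type": "string", "format": "date-time"}
      }
    },
    {
      "type": "object",
      "required": ["type", "patient_id", "time", "system", "code"],
      "properties": {
        "type": {"const": "event"},
        "patient_id": {"type": "string"},
        "time": {"type": "string", "format": "date-time"},
        "system": {"enum": ["SNOMED", "LOINC", "DIVI_QI_S"]},
        "code": {"type": "string"},
        "value": {"type": "number"},
        "unit": {"type": "string"},
        "end_time": {"type": "string", "format": "date-time"}
      }
    }
  ]
}
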