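{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Quality-indicator catalog",
  "description": "Shape of the catalog fixtures (concepts.yaml + indicators.yaml, or the compiled single-file catalog JSON). The typed loaders enforce these constraints; this document is the published reference.",
  "type": "object",
  "required": ["concepts", "indicators"],
  "properties": {
    "concepts": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["key", "display", "codings"],
        "properties": {
          "key": {"type": "string", "minLength": 1},
          "display": {"type": "string"},
          "codings": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["system", "code", "display"],
              "properties": {
                "system": {"enum": ["SNOMED", "LOINC", "DIVI_QI_S"]},
                "code": {"type": "string", "minLength": 1},
                "display": {"type": "string", "minLength": 1},
                "omop_id": {"type": "integer"}
              }
            }
          }
        }
      }
    },
    "indicators": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["qi", "sub_id", "title", "type"],
        "properties": {
          "qi": {"type": "integer", "minimum": 1, "maximum": 10},
          "sub_id": {"type": "string", "pattern": "^[0-9]+[a-z]$"},
          "title": {"type": "string"},
          "type": {"enum": ["process", "outcome", "structure"]},
          "narrative": {"type": "string"},
          "plans": {"type": "array", "items": {"$ref": "#/$defs/plan"}}
        }
      }
    }
  },
  "$defs": {
    "comparator": {
      "type": "object",
      "required": ["op", "value"],
      "properties": {
        "op": {"enum": ["EQ", "NE", "LT", "LE", "GT", "GE", "RANGE"]},
        "value": {"type": "number"},
        "value_high": {"type": "number"},
        "unit": {"type": "string"}
      }
    },
    "expr": {
      "type": "object",
      "oneOf": [
        {
          "required": ["atom"],
          "properties": {
            "atom": {"type": "string"},
            "cmp": {"$ref": "#/$defs/comparator"},
            "history": {"type": "boolean"}
          }
        },
        {"required": ["not"], "properties": {"not": {"$ref": "#/$defs/expr"}}},
        {"required": ["all"], "properties": {"all": {"type": "array", "items": {"$ref": "#/$defs/expr"}}}},
        {"required": ["any"], "properties": {"any": {"type": "array", "items": {"$ref": "#/$defs/expr"}}}},
        {"required": ["one_or_more"], "properties": {"one_or_more": {"type": "array", "items": {"$ref": "#/$defs/expr"}}}},
        {"required": ["at_least"], "properties": {"at_least": {"$ref": "#/$defs/counted"}}},
        {"required": ["exactly"], "properties": {"exactly": {"$ref": "#/$defs/counted"}}}
      ]
    },
    "counted": {
      "type": "object",
      "required": ["n", "of"],
      "properties": {
        "n": {"type": "integer", "minimum": 1},
        "of": {"type": "array", "items": {"$ref": "#/$defs/expr"}}
      }
    },
    "timing": {
      "type": "object",
      "required": ["kind"],
      "properties": {
        "kind": {"enum": ["PER_DAY", "PER_SHIFT", "PER_WEEK", "WITHIN_HOURS_OF_ADMISSION", "ONCE_PER_STAY"]},
        "n": {"type": "integer", "minimum": 1},
        "hours": {"type": "number", "exclusiveMinimum": 0}
      }
    },
    "item": {
      "type": "object",
      "oneOf": [
        {
          "required": ["action"],
          "properties": {
            "action": {
              "type": "object",
              "required": ["concept", "timing"],
              "properties": {
                "concept": {"type": "string"},
                "timing": {"$ref": "#/$defs/timing"},
                "negated": {"type": "boolean"}
              }
            }
          }
        },
        {
          "required": ["goal"],
          "properties": {
            "goal": {
              "type": "object",
              "required": ["concept", "cmp"],
              "properties": {
                "concept": {"type": "string"},
                "cmp": {"$ref": "#/$defs/comparator"}
              }
            }
          }
        },
        {
          "required": ["rate"],
          "properties": {
            "rate": {
              "type": "object",
              "required": ["concept"],
              "properties": {
                "concept": {"type": "string"},
                "threshold": {"$ref": "#/$defs/comparator"}
              }
            }
          }
        }
      ]
    },
    "plan": {
      "type": "object",
      "required": ["id", "evaluation_unit", "population", "intervention"],
      "properties": {
        "id": {"type": "string"},
        "evaluation_unit": {"enum": ["PATIENT_DAY", "STAY", "COHORT_PERIOD"]},
        "population": {"$ref": "#/$defs/expr"},
        "intervention": {
          "type": "object",
          "required": ["method", "items"],
          "properties": {
            "method": {"enum": ["ALL", "ANY", "AT_LEAST", "EXACTLY", "ONE_OR_MORE"]},
            "n": {"type": "integer", "minimum": 1},
            "items": {"type": "array", "minItems": 1, "items": {"$ref": "#/$defs/item"}}
          }
        }
      }
    }
  }
}
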