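{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "HSM model description",
  "type": "object",
  "required": ["name", "substances", "sites", "control_functions", "generators"],
  "properties": {
    "name": {"type": "string"},
    "version": {"type": "string"},
    "substances": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "properties": {"id": {"type": "string"}, "role": {"type": "string"}}
      }
    },
    "sites": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "ligands"],
        "properties": {
          "id": {"type": "string"},
          "ligands": {"type": "array", "items": {"type": "string"}, "minItems": 1, "maxItems": 2}
        }
      }
    },
    "control_functions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "inputs", "table"],
        "properties": {
          "id": {"type": "string"},
          "inputs": {"type": "array", "items": {"type": "string"}},
          "table": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["states", "level"],
              "properties": {
                "states": {
                  "type": "array",
                  "items": {"type": "string", "pattern": "^(FREE|BOUND:.+)$"}
                },
                "level": {"type": "integer", "minimum": 0}
              }
            }
          }
        }
      }
    },
    "generators": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "product", "control"],
        "properties": {
          "id": {"type": "string"},
          "product": {"type": "string"},
          "control": {"type": "string"},
          "growth_rate": {"type": ["number", "null"], "exclusiveMinimum": 0},
          "degradation_rate": {"type": ["number", "null"], "exclusiveMinimum": 0}
        }
      }
    }
  }
}
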