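{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "ssimod module definition",
  "type": "object",
  "additionalProperties": false,
  "required": ["schema_version", "nodes", "reactions"],
  "properties": {
    "schema_version": {"const": 1},
    "name": {"type": "string"},
    "allow_ssn": {"type": "boolean"},
    "nodes": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "role": {"enum": ["input", "output", "state"]}
        }
      }
    },
    "reactions": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["id", "substrate", "product", "v_max"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "substrate": {"type": "string"},
          "product": {"type": "string"},
          "v_max": {"type": "number", "exclusiveMinimum": 0},
          "k_m": {"type": "number", "exclusiveMinimum": 0},
          "k": {"type": "number", "exclusiveMinimum": 0},
          "n": {"type": "number", "minimum": 1},
          "inhibitors": {
            "type": "array",
            "items": {
              "type": "object",
              "additionalProperties": false,
              "required": ["id", "k_c", "k_u"],
              "properties": {
                "id": {"type": "string"},
                "k_c": {"type": "number", "exclusiveMinimum": 0},
                "k_u": {"type": "number", "exclusiveMinimum": 0}
              }
            }
          }
        }
      }
    },
    "inputs": {
      "type": "object",
      "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
    },
    "analysis": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "bounds": {
          "type": "array",
          "minItems": 2,
          "maxItems": 2,
          "items": {"type": "number", "exclusiveMinimum": 0}
        },
        "n_starts": {"type": "integer", "minimum": 0},
        "lattice_points": {"type": "integer", "minimum": 2},
        "seed": {"type": "integer"},
        "t_end": {"type": "number", "exclusiveMinimum": 0}
      }
    }
  }
}
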