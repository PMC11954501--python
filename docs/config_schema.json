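{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "nmalab run configuration",
  "type": "object",
  "required": ["inputs", "outcomes"],
  "properties": {
    "inputs": {
      "type": "object",
      "description": "Paths to input CSVs, keyed by kind.",
      "properties": {
        "contrasts": {"type": "string"},
        "arms": {"type": "string"},
        "ae_arms": {"type": "string"},
        "km_points": {"type": "string"},
        "km_risk": {"type": "string"},
        "km_meta": {"type": "string"}
      },
      "additionalProperties": false
    },
    "outcomes": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "scale", "direction", "data"],
        "properties": {
          "name": {"type": "string"},
          "scale": {"enum": ["log_hr", "log_or", "ae"]},
          "direction": {"enum": ["lower_better", "higher_better"]},
          "data": {"enum": ["contrasts", "arms", "ae_arms"]},
          "note": {"type": "string"}
        },
        "additionalProperties": false
      }
    },
    "reference": {"type": ["string", "null"]},
    "merges": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["from", "to"],
        "properties": {
          "from": {"type": "array", "items": {"type": "string"}},
          "to": {"type": "string"}
        }
      }
    },
    "priors": {
      "type": "object",
      "properties": {
        "d_sd": {"type": "number", "exclusiveMinimum": 0},
        "tau2_lognormal": {
          "type": "array", "minItems": 2, "maxItems": 2,
          "items": {"type": "number"}
        }
      }
    },
    "mcmc": {
      "type": "object",
      "properties": {
        "burn": {"type": "integer", "minimum": 1},
        "sample": {"type": "integer", "minimum": 1},
        "chains": {"type": "integer", "minimum": 2},
        "seed": {"type": "integer"},
        "thin": {"type": "integer", "minimum": 1}
      }
    },
    "sensitivity_exclusions": {
      "type": "array", "items": {"type": "string"},
      "description": "Trial ids removed one at a time in re-runs."
    },
    "output_dir": {"type": "string"},
    "seed": {"type": "integer"}
  }
}
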