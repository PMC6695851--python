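{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "avfppg evaluation report",
  "type": "object",
  "required": ["task", "seed", "n_subjects", "classifiers"],
  "properties": {
    "task": {"type": "string", "enum": ["dos", "bfv"]},
    "seed": {"type": "integer"},
    "n_subjects": {"type": "integer", "minimum": 1},
    "classifiers": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["pooled", "metrics", "selected_params"],
        "properties": {
          "pooled": {
            "type": "object",
            "required": ["tp", "fp", "fn", "tn"],
            "properties": {
              "tp": {"type": "integer", "minimum": 0},
              "fp": {"type": "integer", "minimum": 0},
              "fn": {"type": "integer", "minimum": 0},
              "tn": {"type": "integer", "minimum": 0}
            }
          },
          "metrics": {"type": "object"},
          "selected_params": {"type": "array"},
          "fold_sizes": {"type": "array"}
        }
      }
    }
  }
}
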