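{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/ocublink/annotation.schema.json",
  "title": "ocublink annotation document",
  "type": "object",
  "required": ["recordings"],
  "properties": {
    "recordings": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["participant_id", "condition", "windows"],
        "properties": {
          "participant_id": {"type": "string"},
          "age_y": {"type": ["integer", "null"], "minimum": 0},
          "gender": {"enum": ["M", "F", null]},
          "condition": {"enum": ["baseline", "display", "hardcopy"]},
          "duration_s": {"type": ["number", "null"], "exclusiveMinimum": 0},
          "windows": {
            "type": "array",
            "minItems": 1,
            "items": {
              "type": "object",
              "required": ["start_s", "end_s", "boundary_policy", "events"],
              "properties": {
                "start_s": {"type": "number"},
                "end_s": {"type": "number"},
                "boundary_policy": {"enum": ["pinned", "assumed"]},
                "events": {
                  "type": "array",
                  "items": {
                    "type": "object",
                    "required": ["time_s", "complete"],
                    "properties": {
                      "time_s": {"type": "number"},
                      "complete": {"type": "boolean"}
                    },
                    "additionalProperties": false
                  }
                }
              },
              "additionalProperties": false
            }
          }
        },
        "additionalProperties": false
      }
    }
  },
  "additionalProperties": false
}
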