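{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "MRCA-age estimate",
  "type": "object",
  "required": ["query", "per_source", "overall_range"],
  "properties": {
    "query": {"type": "array", "items": {"type": "string"}},
    "per_source": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "citation", "mrca_age", "n_matched", "sample_ages"],
        "properties": {
          "id": {"type": "string"},
          "citation": {"type": "string"},
          "mrca_age": {"type": "number", "minimum": 0},
          "n_matched": {"type": "integer", "minimum": 2},
          "sample_ages": {"type": "array", "items": {"type": "number"}},
          "sample_summary": {
            "type": "object",
            "required": ["min", "median", "max"],
            "properties": {
              "min": {"type": "number"},
              "median": {"type": "number"},
              "max": {"type": "number"}
            }
          }
        }
      }
    },
    "no_estimate": {"type": "array", "items": {"type": "string"}},
    "overall_range": {"type": "array", "items": {"type": "number"}}
  }
}
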