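{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Name-resolution report",
  "type": "object",
  "required": ["status", "names"],
  "properties": {
    "status": {"type": "string", "enum": ["pending", "done"]},
    "names": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["submittedName", "matches"],
        "properties": {
          "submittedName": {"type": "string"},
          "matches": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["matchedName", "score", "sourceId", "uri"],
              "properties": {
                "matchedName": {"type": "string"},
                "score": {"type": "number", "minimum": 0, "maximum": 1},
                "sourceId": {"type": "string"},
                "uri": {"type": "string"}
              }
            }
          }
        }
      }
    }
  }
}
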