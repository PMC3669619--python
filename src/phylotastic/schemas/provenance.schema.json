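{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Pipeline provenance record",
  "type": "object",
  "required": ["source_tree", "citation", "operations", "name_decisions",
               "ledger", "timestamp", "tool_version"],
  "properties": {
    "source_tree": {"type": "string"},
    "citation": {"type": "string"},
    "operations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["stage", "parameters"],
        "properties": {
          "stage": {"type": "string",
                    "enum": ["resolve", "select", "graft", "prune", "scale"]},
          "parameters": {"type": "object"}
        }
      }
    },
    "name_decisions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["submitted", "outcome"],
        "properties": {
          "submitted": {"type": "string"},
          "matched": {"type": ["string", "null"]},
          "score": {"type": ["number", "null"]},
          "source": {"type": ["string", "null"]},
          "outcome": {"type": "string",
                      "enum": ["kept", "unresolved", "dropped_ambiguous"]},
          "ambiguous": {"type": "boolean"}
        }
      }
    },
    "ledger": {
      "type": "object",
      "required": ["submitted", "resolved_kept", "unresolved",
                   "in_output_tree", "not_in_source_tree"],
      "properties": {
        "submitted": {"type": "integer", "minimum": 0},
        "resolved_kept": {"type": "integer", "minimum": 0},
        "unresolved": {"type": "integer", "minimum": 0},
        "in_output_tree": {"type": "integer", "minimum": 0},
        "not_in_source_tree": {"type": "integer", "minimum": 0}
      }
    },
    "timestamp": {"type": "string"},
    "tool_version": {"type": "string"}
  }
}
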