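{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "diapath rule file",
  "description": "A JSON array of condition-action rules over the patient fact base. Validation in diapath is performed by diapath.rulebase.load_rulebase; this schema documents the contract.",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["rule_id", "module", "provenance", "conditions", "actions"],
    "additionalProperties": false,
    "properties": {
      "rule_id": {"type": "string"},
      "module": {
        "enum": ["diagnosis_patterns", "risk_assessment", "control_objectives",
                 "hierarchical_management", "self_monitoring", "regular_follow_up",
                 "abnormal_attention", "medication_guidance", "lifestyle_guidance",
                 "compliance_management"]
      },
      "provenance": {"enum": ["expert", "guideline", "both"]},
      "priority": {"type": "integer", "default": 0},
      "conditions": {
        "type": "array",
        "minItems": 1,
        "items": {
          "type": "object",
          "required": ["predicate", "comparator"],
          "properties": {
            "predicate": {"type": "string"},
            "comparator": {"enum": ["<", "<=", "=", ">=", ">", "in", "present", "absent"]},
            "operand": {}
          }
        }
      },
      "actions": {
        "type": "array",
        "minItems": 1,
        "items": {
          "type": "object",
          "required": ["predicate", "value"],
          "properties": {
            "predicate": {"type": "string"},
            "value": {}
          }
        }
      }
    }
  }
}
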