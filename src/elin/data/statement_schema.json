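{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Causal statement file",
  "description": "JSON array of text-mined causal relationships between grounded biological entities.",
  "type": "array",
  "items": {
    "type": "object",
    "required": ["type", "subj", "obj", "period"],
    "properties": {
      "type": {
        "enum": ["Activation", "Inhibition", "IncreaseAmount", "DecreaseAmount", "Complex", "Association"]
      },
      "subj": {"$ref": "#/$defs/entity"},
      "obj": {"$ref": "#/$defs/entity"},
      "evidence_count": {"type": "integer", "minimum": 1, "default": 1},
      "pmids": {"type": "array", "items": {"type": "string"}},
      "period": {"enum": ["EG", "MG", "LG", "BIRTH", "NEWBORN", "INFANT"]}
    }
  },
  "$defs": {
    "entity": {
      "type": "object",
      "required": ["name"],
      "properties": {
        "name": {"type": "string"},
        "db_refs": {
          "type": "object",
          "additionalProperties": {"type": "string"},
          "description": "namespace -> identifier; HGNC, FPLX, CHEBI, GO, MESH, DOID, UMLS (TEXT ignored)"
        },
        "kind": {
          "enum": ["bioprocess", "gene"],
          "description": "optional layer hint for ungrounded entities"
        }
      }
    }
  }
}
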