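{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "kb-snapshot.schema.json",
  "title": "Knowledgebase snapshot",
  "description": "Single-document snapshot: one top-level array per entity type. Link fields hold integer public identifiers resolved after parsing.",
  "type": "object",
  "properties": {
    "format": {"const": "kb-snapshot"},
    "version": {"const": 1},
    "reference_build": {"type": "string", "default": "GRCh37"},
    "genes": {"type": "array", "items": {"$ref": "#/$defs/gene"}},
    "variants": {"type": "array", "items": {"$ref": "#/$defs/variant"}},
    "variant_groups": {"type": "array", "items": {"$ref": "#/$defs/stub"}},
    "evidence_items": {"type": "array", "items": {"$ref": "#/$defs/evidence"}},
    "assertions": {"type": "array", "items": {"$ref": "#/$defs/assertion"}},
    "sources": {"type": "array", "items": {"$ref": "#/$defs/source"}},
    "users": {"type": "array", "items": {"$ref": "#/$defs/stub"}},
    "organizations": {"type": "array", "items": {"$ref": "#/$defs/stub"}}
  },
  "additionalProperties": false,
  "$defs": {
    "id": {"type": "integer", "minimum": 1},
    "status": {"enum": ["accepted", "submitted", "rejected"]},
    "blob": {"type": "object"},
    "stub": {
      "type": "object",
      "properties": {"id": {"$ref": "#/$defs/id"}},
      "required": ["id"]
    },
    "coordinates": {
      "type": "object",
      "properties": {
        "chromosome": {"type": "string"},
        "start": {"$ref": "#/$defs/id"},
        "stop": {"$ref": "#/$defs/id"},
        "reference_bases": {"type": "string", "pattern": "^[ACGTNacgtn]+$"},
        "variant_bases": {"type": "string", "pattern": "^[ACGTNacgtn]+$"},
        "chromosome2": {"type": "string"},
        "start2": {"$ref": "#/$defs/id"},
        "stop2": {"$ref": "#/$defs/id"},
        "representative_transcript": {"type": "string"}
      },
      "additionalProperties": false,
      "dependentRequired": {"chromosome2": ["start2", "stop2"]}
    },
    "gene": {
      "type": "object",
      "properties": {
        "id": {"$ref": "#/$defs/id"},
        "name": {"type": "string"},
        "aliases": {"type": "array", "items": {"type": "string"}},
        "description": {"type": "string"}
      },
      "required": ["id"]
    },
    "variant": {
      "type": "object",
      "properties": {
        "id": {"$ref": "#/$defs/id"},
        "gene_id": {"$ref": "#/$defs/id"},
        "name": {"type": "string"},
        "aliases": {"type": "array", "items": {"type": "string"}},
        "coordinates": {"$ref": "#/$defs/coordinates"},
        "variant_types": {"type": "array", "items": {"type": "string"}}
      },
      "required": ["id"]
    },
    "evidence": {
      "type": "object",
      "properties": {
        "id": {"$ref": "#/$defs/id"},
        "variant_id": {"$ref": "#/$defs/id"},
        "status": {"$ref": "#/$defs/status"},
        "evidence_level": {"enum": ["A", "B", "C", "D", "E"]},
        "evidence_direction": {"type": "string"},
        "clinical_significance": {"type": "string"},
        "disease": {"$ref": "#/$defs/blob"},
        "drugs": {"type": "array", "items": {"$ref": "#/$defs/blob"}},
        "source_id": {"$ref": "#/$defs/id"},
        "rating": {"type": "integer", "minimum": 1, "maximum": 5}
      },
      "required": ["id"]
    },
    "assertion": {
      "type": "object",
      "properties": {
        "id": {"$ref": "#/$defs/id"},
        "variant_id": {"$ref": "#/$defs/id"},
        "status": {"$ref": "#/$defs/status"},
        "amp_category": {"type": "string"},
        "evidence_ids": {"type": "array", "items": {"$ref": "#/$defs/id"}},
        "disease": {"$ref": "#/$defs/blob"},
        "drugs": {"type": "array", "items": {"$ref": "#/$defs/blob"}}
      },
      "required": ["id"]
    },
    "source": {
      "type": "object",
      "properties": {
        "id": {"$ref": "#/$defs/id"},
        "citation": {"type": "string"},
        "source_type": {"type": "string"}
      },
      "required": ["id"]
    }
  }
}
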