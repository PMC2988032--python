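{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "$id": "mtqc-report/1",
  "title": "mtqc combined QC report",
  "type": "object",
  "required": ["schema", "pairs", "mixtures"],
  "properties": {
    "schema": {"const": "mtqc-report/1"},
    "pairs": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "patient", "normal_call", "tumor_call", "divergence",
          "somatic_diffs", "lineage_explained_fraction", "verdict"
        ],
        "properties": {
          "patient": {"type": "string"},
          "normal_call": {"$ref": "#/definitions/call"},
          "tumor_call": {"$ref": "#/definitions/call"},
          "divergence": {"type": "integer", "minimum": 0},
          "somatic_diffs": {"type": "array", "items": {"type": "string"}},
          "lineage_explained_fraction": {"type": "number", "minimum": 0, "maximum": 1},
          "verdict": {"enum": ["CONCORDANT", "SUSPECT_MIXUP", "INDETERMINATE"]}
        }
      }
    },
    "mixtures": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "sample", "components", "assignment", "explained_fraction_k1",
          "explained_fraction_k2", "gain", "is_mixture", "pair_ranking"
        ],
        "properties": {
          "sample": {"type": "string"},
          "components": {"type": "array", "items": {"type": "string"}, "maxItems": 2},
          "assignment": {
            "type": "object",
            "additionalProperties": {"enum": ["component1", "component2", "residual"]}
          },
          "explained_fraction_k1": {"type": "number", "minimum": 0, "maximum": 1},
          "explained_fraction_k2": {"type": "number", "minimum": 0, "maximum": 1},
          "gain": {"type": "number"},
          "is_mixture": {"type": "boolean"},
          "pair_ranking": {
            "type": "array",
            "items": {
              "type": "array",
              "items": [{"type": "string"}, {"type": "string"}, {"type": "number"}]
            }
          }
        }
      }
    }
  },
  "definitions": {
    "call": {
      "type": "object",
      "required": ["haplogroup", "score", "matched", "missing", "private"],
      "properties": {
        "haplogroup": {"type": "string"},
        "score": {"type": "number", "minimum": 0, "maximum": 1},
        "matched": {"type": "array", "items": {"type": "string"}},
        "missing": {"type": "array", "items": {"type": "string"}},
        "private": {"type": "array", "items": {"type": "string"}}
      }
    }
  }
}
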