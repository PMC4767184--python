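{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "dcekinetics pipeline report",
  "type": "object",
  "required": ["schema_version", "n_subjects", "groups", "tic_types", "comparison"],
  "additionalProperties": true,
  "properties": {
    "schema_version": {"type": "integer", "const": 1},
    "seed": {"type": ["integer", "null"]},
    "n_subjects": {"type": "integer", "minimum": 1},
    "groups": {"type": "array", "items": {"type": "string"}},
    "tic_types": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["I", "II", "III"],
        "properties": {
          "I": {"type": "integer", "minimum": 0},
          "II": {"type": "integer", "minimum": 0},
          "III": {"type": "integer", "minimum": 0}
        }
      }
    },
    "comparison": {
      "type": ["object", "null"],
      "required": ["alpha", "groups", "parameters"],
      "properties": {
        "alpha": {"type": "number"},
        "groups": {"type": "array", "items": {"type": "string"}},
        "parameters": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["parameter", "route", "statistic", "p", "significant"],
            "properties": {
              "parameter": {"type": "string"},
              "route": {"type": "string", "enum": ["anova", "kruskal-wallis"]},
              "homogeneity_p": {"type": "number"},
              "statistic": {"type": "number"},
              "df": {"type": "array", "items": {"type": "integer"}},
              "p": {"type": "number", "minimum": 0, "maximum": 1},
              "p_formatted": {"type": "string"},
              "significant": {"type": "boolean"},
              "group_means": {"type": "object"},
              "group_sds": {"type": "object"},
              "mean_ranks": {"type": ["object", "null"]},
              "pairwise": {"type": ["object", "null"]}
            }
          }
        }
      }
    }
  }
}
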