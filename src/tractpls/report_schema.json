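{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "tractpls analysis report",
  "type": "object",
  "required": ["provenance", "univariate", "em_plsc", "maturity", "associations", "interactions"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["version", "seed", "n_perm", "n_boot", "alpha", "config_hash"],
      "properties": {
        "version": {"type": "string"},
        "seed": {"type": "integer"},
        "n_perm": {"type": "integer"},
        "n_boot": {"type": "integer"},
        "alpha": {"type": "number"},
        "bf_method": {"type": "string"},
        "age_cutoff": {"type": "number"},
        "config_hash": {"type": "string"}
      }
    },
    "univariate": {
      "type": "object",
      "required": ["em_age_regressions"],
      "properties": {
        "em_age_regressions": {"type": "object"}
      }
    },
    "em_plsc": {"type": "object"},
    "maturity": {"type": "object"},
    "associations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["tract", "behavior", "panel", "r", "p_raw", "p_fdr", "n"],
        "properties": {
          "tract": {"type": "string"},
          "behavior": {"type": "string"},
          "panel": {"type": "string"},
          "r": {"type": "number"},
          "p_raw": {"type": "number"},
          "p_fdr": {"type": "number"},
          "n": {"type": "integer"}
        }
      }
    },
    "interactions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["tract", "behavior", "cutoff", "slope_young", "slope_old", "interaction_coefficient", "interaction_p"],
        "properties": {
          "tract": {"type": "string"},
          "behavior": {"type": "string"},
          "cutoff": {"type": "number"},
          "slope_young": {"type": "number"},
          "slope_old": {"type": "number"},
          "interaction_coefficient": {"type": "number"},
          "interaction_p": {"type": "number"}
        }
      }
    }
  }
}
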