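{
  "type": "object",
  "required": ["site", "species", "criterion", "c_hat", "gof", "model_table", "log"],
  "properties": {
    "site": {"type": "string"},
    "species": {"type": "string"},
    "criterion": {"type": "string"},
    "c_hat": {"type": "number"},
    "best_model": {"type": "string"},
    "gof": {
      "type": "object",
      "required": ["failed", "chi2", "df", "components"],
      "properties": {
        "failed": {"type": "boolean"},
        "chi2": {"type": "number"},
        "df": {"type": "number"},
        "components": {"type": "object"}
      }
    },
    "model_table": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["model", "converged"],
        "properties": {
          "model": {"type": "string"},
          "n_par": {"type": "number"},
          "loglik": {"type": "number"},
          "aic": {"type": "number"},
          "qaic": {"type": "number"},
          "converged": {"type": "boolean"}
        }
      }
    },
    "abundance": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["primary", "n"],
        "properties": {
          "primary": {"type": "number"},
          "season": {"type": "string"},
          "n": {"type": "number"},
          "p_star": {"type": "number"},
          "N_hat": {"type": "number"},
          "se": {"type": "number"},
          "lo": {"type": "number"},
          "hi": {"type": "number"}
        }
      }
    },
    "annual_survival": {
      "type": "object",
      "required": ["estimate"],
      "properties": {
        "estimate": {"type": "number"},
        "lo": {"type": "number"},
        "hi": {"type": "number"}
      }
    },
    "summary": {
      "type": "object",
      "required": ["relative_change", "t_years"],
      "properties": {
        "relative_change": {"type": "array"},
        "average_annual_growth_pct": {"type": "number"},
        "t_years": {"type": "number"},
        "cv": {"type": "number"}
      }
    },
    "log": {"type": "array", "items": {"type": "string"}}
  }
}
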