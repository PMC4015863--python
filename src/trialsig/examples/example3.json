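{
  "schema_version": "1",
  "title": "Hydroxyethyl starch versus Ringer's acetate in severe sepsis",
  "design": {
    "outcome_type": "binary",
    "effect": {"type": "rr", "value": 0.8, "systematic_review_based": false},
    "control_risk": 0.5,
    "alpha": 0.05,
    "power": 0.8,
    "planned_n_total": 800
  },
  "n_randomised": 804,
  "outcomes": [
    {
      "id": "death_or_end_stage_kidney_failure",
      "role": "primary",
      "result": {
        "events_experimental": 202,
        "n_experimental": 396,
        "events_control": 173,
        "n_control": 402
      },
      "direction_of_benefit": "less_than_null",
      "timepoints_assessed": 1
    }
  ],
  "multiplicity": {"procedure": "none"},
  "bf_threshold": 0.1,
  "p_threshold": 0.05
}
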