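{
  "schema_version": "1",
  "title": "Tranexamic acid in trauma patients with significant haemorrhage",
  "design": {
    "outcome_type": "binary",
    "effect": {"type": "rr", "value": 0.9, "systematic_review_based": false},
    "control_risk": 0.2,
    "alpha": 0.05,
    "power": 0.8,
    "planned_n_total": 20000
  },
  "n_randomised": 20211,
  "outcomes": [
    {
      "id": "all_cause_mortality",
      "role": "primary",
      "result": {
        "measure": "or",
        "estimate": 0.89,
        "p": 0.0035
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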