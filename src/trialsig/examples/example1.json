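{
  "schema_version": "1",
  "title": "Multivitamins for the prevention of total cancer",
  "design": {
    "outcome_type": "binary",
    "effect": {"type": "or", "value": 0.8, "systematic_review_based": false},
    "alpha": 0.05,
    "power": 0.8,
    "planned_n_total": 15000
  },
  "n_randomised": 14641,
  "outcomes": [
    {
      "id": "total_cancer",
      "role": "secondary",
      "result": {
        "measure": "hr",
        "estimate": 0.92,
        "ci_lower": 0.86,
        "ci_upper": 0.998,
        "ci_level": 0.95,
        "p": 0.04
      },
      "direction_of_benefit": "less_than_null"
    },
    {"id": "prostate_cancer", "role": "secondary"},
    {"id": "cardiovascular_events", "role": "secondary"},
    {"id": "macular_degeneration", "role": "secondary"},
    {"id": "cataract", "role": "secondary"}
  ],
  "multiplicity": {"procedure": "none"},
  "extra_alternatives": [
    {"type": "or", "value": 0.7, "systematic_review_based": false}
  ],
  "bf_threshold": 0.1,
  "p_threshold": 0.05
}
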