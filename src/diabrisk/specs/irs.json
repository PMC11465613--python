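{
  "name": "IRS",
  "form": "points",
  "items": [
    {"predictor": "age", "kind": "threshold_points", "cut_points": [35.0, 50.0], "values": [0.0, 20.0, 30.0]},
    {"predictor": "waist_circumference", "kind": "threshold_points", "cut_points": [80.0, 90.0], "values": [0.0, 10.0, 20.0]},
    {"predictor": "physical_activity", "kind": "categorical_points", "values": {"1": 30.0, "2": 20.0, "3": 0.0}},
    {"predictor": "family_history_dm", "kind": "categorical_points", "values": {"yes": 10.0, "no": 0.0}}
  ],
  "probability_link": {"kind": "score_logistic", "a": -3.85, "b": 0.027},
  "description": "Indian Diabetes Risk Score: age, waist circumference, physical activity grade and family history. The only score in the menu without a hypertension item.",
  "citation": "Mohan V et al. A simplified Indian Diabetes Risk Score for screening for undiagnosed diabetic subjects (CURES). J Assoc Physicians India 2005. Probability link fitted provisionally to the published risk-per-score table.",
  "provisional": true
}
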