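{
  "name": "ADA",
  "form": "points",
  "items": [
    {"predictor": "age", "kind": "threshold_points", "cut_points": [40.0, 50.0, 60.0], "values": [0.0, 1.0, 2.0, 3.0]},
    {"predictor": "sex", "kind": "categorical_points", "values": {"male": 1.0, "female": 0.0}},
    {"predictor": "family_history_dm", "kind": "categorical_points", "values": {"yes": 1.0, "no": 0.0}},
    {"predictor": "hypertension_composite", "kind": "categorical_points", "values": {"yes": 1.0, "no": 0.0}},
    {"predictor": "bmi", "kind": "threshold_points", "cut_points": [25.0, 30.0, 40.0], "values": [0.0, 1.0, 2.0, 3.0]},
    {"predictor": "physical_activity", "kind": "categorical_points", "values": {"1": 1.0, "2": 0.0, "3": 0.0}}
  ],
  "probability_link": {"kind": "score_logistic", "a": -1.2, "b": 0.65},
  "description": "American Diabetes Association risk test: age, sex, family history, hypertension, BMI category and physical inactivity. Developed in a high-prevalence multi-ethnic population; its probability link sits far above African screening prevalences, producing the characteristic gross overestimation.",
  "citation": "Bang H et al. Development and validation of a patient self-assessment score for diabetes risk. Ann Intern Med 2009. Probability link fitted provisionally to the published risk-per-score table.",
  "provisional": true
}
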