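{
  "name": "SIMPLIFIED_FINDRISC",
  "form": "points",
  "items": [
    {"predictor": "age", "kind": "threshold_points", "cut_points": [45.0, 55.0, 65.0], "values": [0.0, 2.0, 3.0, 4.0]},
    {"predictor": "bmi", "kind": "threshold_points", "cut_points": [25.0, 30.0], "values": [0.0, 1.0, 3.0]},
    {"predictor": "waist_circumference", "kind": "threshold_points", "cut_points": [94.0, 102.0], "values": [0.0, 3.0, 4.0],
     "sex_specific": {"female": [80.0, 88.0], "male": [94.0, 102.0]}},
    {"predictor": "bp_medication", "kind": "categorical_points", "values": {"yes": 2.0, "no": 0.0}},
    {"predictor": "physical_activity", "kind": "categorical_points", "values": {"1": 2.0, "2": 0.0, "3": 0.0}}
  ],
  "probability_link": {"kind": "score_logistic", "a": -4.8, "b": 0.22},
  "description": "Simplified FINDRISC: age, BMI, sex-specific waist circumference, antihypertensive medication (the only hypertension signal this score uses) and physical inactivity. The source model's history-of-high-blood-glucose item has no column in the cohort dictionary and is omitted; the transcription is provisional.",
  "citation": "Bergmann A et al. A simplified Finnish diabetes risk score to predict type 2 diabetes risk and disease evolution in a German population. Horm Metab Res 2007. Probability link fitted provisionally to the published risk-per-score table.",
  "provisional": true
}
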