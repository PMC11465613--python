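{
  "name": "ADRS",
  "form": "logistic",
  "intercept": -9.3,
  "items": [
    {"predictor": "age", "kind": "linear_coefficient", "coefficient": 0.045},
    {"predictor": "waist_circumference", "kind": "linear_coefficient", "coefficient": 0.035},
    {"predictor": "hypertension_composite", "kind": "categorical_points", "values": {"yes": 0.55, "no": 0.0}}
  ],
  "probability_link": {"kind": "direct_logistic"},
  "description": "African Diabetes Risk Score: age, waist circumference and hypertensive status (composite definition: self-report, BP medication or measured BP >= 140/90).",
  "citation": "Mayige M. Derivation and validation of a simple risk score for undiagnosed diabetes for Tanzania and other African populations. The score itself is unpublished; coefficients here are a provisional synthetic transcription.",
  "provisional": true
}
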