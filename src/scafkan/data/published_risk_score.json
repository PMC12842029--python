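{
  "version": "1.0",
  "description": "Published 10-feature linear SCAF risk score (logistic student distilled from the dual-path teacher). Score = sum(coef * transform(feature)) + intercept; probability = sigmoid(score); high risk if probability > 0.5.",
  "threshold": 0.5,
  "intercept": -17.815156,
  "terms": [
    {"feature": "lad", "unit": "mm", "transform": "identity", "coef": 0.407314},
    {"feature": "male_gender", "unit": "", "transform": "identity", "coef": -1.810896},
    {"feature": "ldh", "unit": "IU/L", "transform": "log1p", "coef": 2.026237},
    {"feature": "bmi", "unit": "kg/m²", "transform": "identity", "coef": -0.128719},
    {"feature": "hypertension", "unit": "", "transform": "identity", "coef": -0.571839},
    {"feature": "lvpw_thickness", "unit": "mm", "transform": "identity", "coef": -0.439865},
    {"feature": "egfr", "unit": "mL/min/1.73 m²", "transform": "identity", "coef": -0.000892},
    {"feature": "septal_e_over_e_prime", "unit": "", "transform": "identity", "coef": 0.005358},
    {"feature": "lvedv", "unit": "mL", "transform": "identity", "coef": -0.023019},
    {"feature": "coronary_heart_disease", "unit": "", "transform": "identity", "coef": -1.335999}
  ]
}
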