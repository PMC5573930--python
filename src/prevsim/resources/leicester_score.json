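{
  "_comment": "Additive diabetes risk score in the Leicester practice-score covariates (age band, sex, ethnicity, family history, BMI band, antihypertensive treatment), scaled so the published invitation threshold of 4.75 applies. Coefficients are package defaults emulating the published score's ranking; replace via config to use an exact published table.",
  "age_bands": [[16, 29, 0.0], [30, 39, 1.0], [40, 49, 2.0], [50, 59, 3.0], [60, 69, 4.0], [70, 200, 5.0]],
  "sex": {"male": 0.5, "female": 0.0},
  "ethnicity": {"white": 0.0, "south_asian": 2.0, "black": 1.5, "other": 1.0},
  "family_history": 1.0,
  "bmi_bands": [[0, 25, 0.0], [25, 30, 1.0], [30, 35, 2.0], [35, 200, 3.0]],
  "antihypertensive": 1.0
}
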