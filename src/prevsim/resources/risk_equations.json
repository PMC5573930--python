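{
  "_comment": "Annual hazard models for disease events and death. Proportional-hazards forms in the covariates of the published CVD (QRISK2-style), Framingham-style heart failure and UKPDS-style microvascular equations; coefficients are package defaults calibrated to plausible UK magnitudes and are swappable via config (see docs/methods.md). Probabilities are 1 - exp(-hazard).",
  "cvd": {
    "h0": 0.002, "age": 0.075, "age_ref": 50.0, "male": 0.35,
    "sbp": 0.012, "sbp_ref": 130.0, "ratio": 0.15, "ratio_ref": 4.0,
    "smoker_ex": 0.15, "smoker_current": 0.60,
    "bmi": 0.02, "bmi_ref": 25.0, "diabetes": 0.65,
    "imd": 0.08, "imd_ref": 3.0
  },
  "chf": {
    "h0": 0.0008, "age": 0.09, "age_ref": 55.0, "male": 0.30,
    "sbp": 0.010, "sbp_ref": 130.0, "bmi": 0.04, "bmi_ref": 25.0,
    "diabetes": 0.80, "cvd": 0.90
  },
  "microvascular": {
    "hba1c": 0.30, "hba1c_ref": 6.5, "duration": 0.03,
    "base": {
      "foot_ulcer": 0.0035, "amputation": 0.0012,
      "blindness": 0.0020, "renal_failure": 0.0007
    }
  },
  "breast_cancer": {"h0": 0.0004, "age": 0.035, "age_ref": 40.0, "bmi": 0.010, "bmi_ref": 25.0},
  "colon_cancer": {"h0": 0.0002, "age": 0.045, "age_ref": 40.0, "bmi": 0.020, "bmi_ref": 25.0},
  "osteoarthritis": {"h0": 0.0015, "age": 0.05, "age_ref": 45.0, "bmi": 0.08, "bmi_ref": 25.0},
  "depression": {"h0": 0.006, "rr_diabetes": 1.8},
  "mortality": {
    "makeham": {"male": 0.0003, "female": 0.0002},
    "a": {"male": 2.0e-05, "female": 1.1e-05},
    "b": {"male": 0.095, "female": 0.098},
    "log_rr": {
      "diabetes": 0.47, "cvd": 0.60, "chf": 1.00, "renal_failure": 1.30,
      "amputation": 0.60, "depression": 0.18, "foot_ulcer": 0.20, "blindness": 0.10
    },
    "cvd_case_fatality": 0.20,
    "cancer_death": {"breast_cancer": 0.04, "colon_cancer": 0.06}
  }
}
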