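name: community
description: Community dietary advice in the most deprived quintile (women's
  cooking-skills class; weight-loss programme for obese men)
payer: nhs
decay_duration: 5
arms:
  - name: cooking_class
    target: {imd_quintile: 5, sex: female}
    coverage: 1.0
    uptake: 0.114
    cost_per_participant: {1: 82.0}
    bundles:
      - name: cooking
        probability: 1.0
        effects:
          bmi: {point: -1.04, low: -1.448, high: -0.632}
          hba1c: {point: -0.009, low: -0.013, high: -0.005}
          sbp: {point: -0.409, low: -0.536, high: -0.238}
  - name: weight_loss
    target: {imd_quintile: 5, sex: male, bmi_gt: 30}
    coverage: 1.0
    uptake: 0.114
    cost_per_participant: {1: 173.0}
    bundles:
      - name: weight_loss
        probability: 1.0
        effects:
          bmi: {point: -1.29, low: -1.796, high: -0.784}
          hba1c: {point: -0.009, low: -0.013, high: -0.005}
          sbp: {point: -0.409, low: -0.536, high: -0.238}
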