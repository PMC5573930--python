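name: workplace
description: Healthy eating promotion in workplace canteens (20% of employed)
payer: nhs
decay_duration: 5
arms:
  - name: covered_workers
    target: {employed: true}
    coverage: 0.2
    uptake: 1.0
    cost_per_target: {1: 4.99}
    bundles:
      - name: fruit_switch
        probability: 0.119
        effects:
          hba1c: {point: -0.063, low: -0.088, high: -0.034}
          sbp: {point: -2.86, low: -3.75, high: -1.67}
      - name: milk_switch
        probability: 0.089
        effects:
          hba1c: {point: -0.0156, low: -0.022, high: -0.009}
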