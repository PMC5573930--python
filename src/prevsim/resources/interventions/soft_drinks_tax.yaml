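name: soft_drinks_tax
description: 20% tax on sugar-sweetened soft drinks (population-wide)
payer: none
decay_duration: 5
arms:
  - name: population
    target: {all: true}
    coverage: 1.0
    uptake: 1.0
    bundles:
      - name: tax
        probability: 1.0
        effects:
          bmi:
            age_bands:
              - [16, 29, -0.23, -0.28, -0.20]
              - [30, 49, -0.05, -0.07, -0.03]
              - [50, 200, 0.00, -0.01, 0.03]
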