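name: retail
description: New supermarket in a deprived urban area (fruit & veg provision)
payer: private
decay_duration: 5
arms:
  - name: deprived_quintile
    target: {imd_quintile: 5}
    coverage: 1.0
    uptake: 1.0
    bundles:
      - name: fruit_veg
        probability: 1.0
        effects:
          hba1c: {point: -0.010, low: -0.014, high: -0.006}
          sbp: {point: -0.46}
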