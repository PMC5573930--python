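# Screening cascade (risk score > 4.75 at vascular checks, HbA1c test) plus
# intensive lifestyle programme for screen-detected IGR.  Participants are
# determined by the cascade, not by the target rule.  Maintenance classes in
# years 2-4 are charged at a configurable cost (default 0).
# The printed total-cholesterol interval does not bracket its point estimate
# (source misprint); it is kept verbatim and flagged.
name: high_risk
description: Screening at vascular checks and intensive lifestyle programme
  for individuals at high diabetes risk (screen-detected IGR)
payer: nhs
decay_duration: 5
screening: true
arms:
  - name: lifestyle_programme
    target: {all: true}
    coverage: 1.0
    uptake: 1.0
    cost_per_participant: {1: 280.0, 2: 0.0, 3: 0.0, 4: 0.0}
    bundles:
      - name: lifestyle
        probability: 1.0
        effects:
          bmi: {point: -0.94, low: -1.265, high: -0.655}
          hba1c: {point: -0.121, low: -0.215, high: -0.045}
          sbp: {point: -4.30, low: -6.11, high: -2.49}
          total_chol: {point: -0.098, low: -0.235, high: -0.125, allow_unbracketed: true}
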