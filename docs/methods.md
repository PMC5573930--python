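# Methods

## Model structure

prevsim is a discrete-time individual-level simulation with yearly
cycles. Each cycle applies, in a fixed, test-pinned order:

1. **Trajectories** — ageing and metabolic drift, plus the (decayed)
   intervention delta and any one-off treatment effect from last cycle's
   new diagnoses;
2. **GP visit** — probabilistic diagnosis of diabetes, hypertension and
   dyslipidaemia above configurable thresholds, which initiates
   treatment;
3. **Annual events** — Bernoulli draws for each disease event and for
   death (CVD case fatality, cancer-specific, all-cause other);
4. **Economics** — NHS/PSS cost, QALY weight and absence days for the
   cycle.

Enrolment — and, for the screening policy, the one-off screening
cascade — happens at the start of the first cycle, so "year 1" of every
intervention is cycle 0. Cycle 0 is undiscounted; cycle *t* is
discounted by 1/(1+r)^t with r = 1.5%/year. People are simulated to
death or age 110 (a censoring cap, not a recorded death). Costs and
QALYs are attributed at the end of each cycle with no half-cycle
correction; someone who dies within a cycle accrues neither that cycle.
Intervention and screening-test costs are the one exception: they are
incurred at delivery and are charged to everyone alive at the start of
the cycle.

### Common random numbers

All stochastic decisions draw from Philox counter-based streams keyed by
`(master seed, channel, cycle)`, indexed by person slot. An intervention
run and its do-nothing twin therefore consume identical uniforms
everywhere the intervention does not reach. This makes incremental
estimates usable at desk-scale cohort sizes and yields an exact null:
with effects and costs zeroed, all deltas are identically zero (this is
asserted in the test suite person-by-person, cycle-by-cycle).

## Synthetic population

The generator is a parametric stand-in for resampling a national health
survey. Demographics (age pyramid, sex, IMD quintile, ethnicity,
smoking, family history) are categorical marginals; the metabolic block
{BMI, HbA1c, SBP, total cholesterol} is a Gaussian copula with
configurable means, SDs and correlation matrix, truncated to
physiological ranges. Two structural features matter downstream:

- **Deprivation gradient** — additive shifts of metabolic means per IMD
  quintile (defaults +0.35 kg/m² BMI and +0.02% HbA1c per quintile step
  above the middle). The equity results of targeted policies arise from
  these baseline differences, not from differential effectiveness.
- **Undiagnosed diabetes** — a configurable fraction (default 2%) starts
  with HbA1c above the diagnostic threshold and no diagnosis. Screening
  derives much of its value from finding these people.

Baseline HbA1c for everyone else is truncated below 6.4% so nobody
starts above the diagnostic threshold undetected unless that fraction
says so. Employment is Bernoulli among under-65s, rescaled so the
overall employed share matches the 56.3% baseline target; people leave
employment at 65 in-simulation.

What the generator does **not** emulate: survey weights, household
structure, secular trends, and the full empirical joint distribution of
a real survey (only first and second moments plus the configured
gradients). Tests passing on synthetic cohorts show the machinery is
correct under the stated distributional assumptions, not that outputs
match any real population.

## Trajectories

Annual drifts are piecewise linear by age band {16–29, 30–49, 50–69,
70+} and sex, plus a person-level Gaussian random slope drawn once at
baseline. The shipped drift values (e.g. BMI +0.10 kg/m²/yr at 30–49,
SBP +0.5 mmHg/yr) are **placeholders** calibrated to plausible UK adult
drift; the longitudinal-cohort growth-curve estimates this design calls
for were not available, and every value is a config parameter.

HbA1c gains an extra slope (default +0.08%/yr) while an undiagnosed
person sits in the IGR band (≥6.0% and <6.5%). A pre-diagnosis
acceleration is documented in longitudinal cohorts as occurring in the
years before crossing the diagnostic threshold; conditioning on a future
crossing is impossible in a forward simulation, so the in-band
formulation is used to produce the same ramp and give screening a
realistic lead time. This is an approximation.

Treatment effects (antihypertensive −10 mmHg SBP, statin −1.0 mmol/L
TC, post-diagnosis diabetes care −0.5% HbA1c) are one-off level shifts
applied in the cycle treatment starts; drift continues from the shifted
level. Factors are truncated to BMI [15, 70], SBP [70, 250], HbA1c
[3.5, 15], TC [1, 15] to prevent runaway drift over lifetimes.

## Risk equations

Events are sampled from annual probabilities `1 − exp(−h)` with
proportional-hazards `h = h0 · exp(linear predictor)`. The covariate
sets follow the published equation families this model class uses — a
QRISK2-style CVD equation (age, sex, SBP, TC/HDL ratio, smoking, BMI,
diabetes, deprivation), a Framingham-style heart-failure equation, and
UKPDS-style microvascular hazards in HbA1c and diabetes duration — but
the shipped coefficients are package defaults calibrated to plausible
UK magnitudes, not transcriptions of the published tables. They live in
`resources/risk_equations.json` and can be replaced wholesale via
config (`equations: {file: ...}`). Positive coefficients on adverse
exposures make every equation monotone non-decreasing in HbA1c, SBP,
BMI and age by construction; the test suite asserts this over profile
grids.

Design choices:

- **Undiagnosed diabetes** carries the same complication and mortality
  hazards as diagnosed diabetes, driven by true HbA1c, without
  treatment effects — high risk while undetected is the mechanism that
  makes case-finding valuable.
- **Cause of death** when several fatal draws fire in one cycle resolves
  CVD > cancer > other (configurable in order constant).
- **Depression** risk rises (RR 1.8) with diabetes *diagnosis* in the
  base case; a sensitivity switch ties it to biological onset instead,
  mirroring the absence-day trigger switch below.
- Background mortality is a Gompertz–Makeham life-table approximation by
  age and sex with condition log-relative-risks on top.
- Events are incident (first occurrence sets a permanent flag); the
  diabetes risk score is an additive table over age band, sex,
  ethnicity, family history, BMI band and antihypertensive treatment,
  emulating the ranking of the published practice score at its 4.75
  invitation threshold.

## Interventions

Definitions are data (YAML): arms with targeting rules, optional random
coverage, uptake, effect bundles with 95% intervals, cost schedules and
payer. Costs charged to `private`/`none` payers never enter the NHS
ledger. Effects are expressed relative to the counterfactual
trajectory: the engine applies the year-on-year difference
`effect × (w(t) − w(t−1))`, so the level equals `effect × w(t)` and
decays to zero at the decay duration (weight-regain, not compounding).
Workplace fruit and milk switches are independent sub-lotteries; a
worker may draw both. One published total-cholesterol interval does not
bracket its point estimate (a misprint in the source table); it is
shipped verbatim behind an explicit `allow_unbracketed` flag. The
high-risk programme's maintenance classes (years 2–4) are a config cost
defaulting to £0.

## Economics

The shipped cost/utility/absence table
(`resources/cost_table.csv`) contains **placeholder** values (the source
estimates are in an unavailable supplement); every acceptance-level
check that depends on magnitudes constructs its own table. Utility is
baseline EQ-5D minus additive condition decrements and an ageing
decrement (0.002/yr aged in-simulation), floored at −0.594. The
diabetes utility decrement attaches to the disease state (diagnosed or
not); the diabetes annual cost attaches to diagnosis, since care is
only delivered once the condition is found.

Employer costs use the friction method: per-condition absence days per
year (capped at a 90-day friction period per person-year) valued at
£90/day while employed, plus a £3,000 recruitment cost per death in
employment, discounted and divided by the baseline employed count.
Wage, friction period and recruitment cost are placeholders. The
`absence_trigger` switch moves diabetes-related absence from diagnosis
(base case) to biological onset (sensitivity).

## Sensitivity analysis

One-way analysis sets a dotted-path config parameter over a grid and
re-runs the comparison with the same seed. PSA samples intervention
effects from Normal(point, (U−L)/3.92) truncated to the printed
interval — a beneficial effect cannot flip sign beyond its far bound —
and optionally uptakes from Beta. Each run draws a fresh cohort from a
per-run seed derived from the master seed; degenerate distributions
reproduce the deterministic comparison exactly. CEAC ties are split
equally among winners (do-nothing included as a zero-delta strategy),
so curves sum to 1 at every willingness-to-pay; the CEAF reports the
argmax of *mean* net benefit with ties broken by strategy name.

## Problem sizes and numerical choices

Package defaults and tests run desk-scale cohorts (2,000–50,000 people;
PSA 20 × 5,000 in tests, 2,000 × 20,000 as the configured default
spec), with event deltas rescaled per 5,000,000 simulated individuals
and the Monte-Carlo standard error of the net benefit reported
alongside. At these sizes the per-person QALY deltas of mild policies
are within Monte-Carlo noise; the exact-null CRN design is what keeps
the comparisons meaningful. Truncation of the metabolic copula uses
clipping (mass at the bounds) for determinism; correlation matrices are
Cholesky-factorised with a 1e-10 jitter; the EQ-5D floor and all
probability draws are clipped to valid ranges.

## Known limitations

- Trajectory drifts, risk-equation coefficients and the economic table
  are placeholder calibrations — results are structurally meaningful
  (signs, orderings, equity patterns, nulls) but absolute magnitudes
  should not be quoted against published estimates without recalibration.
- One screening round only; no repeat vascular checks (config hook
  pending).
- One intervention per scenario; no layering of policies.
- No physical-activity pathway, smoking/alcohol policies, dementia, or
  unrelated-survivor healthcare costs; no societal perspective beyond
  employer costs.
- Employment is static apart from retirement at 65; no re-entry,
  part-time work or presenteeism.
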