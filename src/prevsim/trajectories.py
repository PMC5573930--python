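"""Yearly metabolic trajectories: BMI, HbA1c, SBP and total cholesterol.

Each risk factor advances once per cycle by a piecewise-linear annual drift
(by age band and sex) plus a person-level random slope drawn once at
baseline, plus any intervention delta (already decayed by the interventions
module), minus a one-off treatment reduction in the cycle a treatment
starts.  HbA1c drifts faster while an undiagnosed person sits in the
impaired-glucose-regulation range, reproducing the pre-diagnosis ramp seen
in longitudinal cohorts and giving screening a realistic lead time.

Shipped drift defaults are placeholders calibrated to plausible UK adult
drift (see docs/methods.md); every value is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AGE_BANDS",
    "TrajectoryParams",
    "DeadIndividualError",
    "advance_metabolic",
    "draw_slopes",
    "hba1c_phase",
]

AGE_BANDS = ((16, 29), (30, 49), (50, 69), (70, 200))

FACTORS = ("bmi", "hba1c", "sbp", "total_chol")


class DeadIndividualError(ValueError):
    """advance_metabolic was called on a dead individual."""


def _default_drift():
    # {factor: {band index: (male, female)}} — annual mean change
    return {
        "bmi": {0: (0.15, 0.15), 1: (0.10, 0.10), 2: (0.03, 0.03), 3: (-0.05, -0.05)},
        "hba1c": {0: (0.010, 0.010), 1: (0.012, 0.012), 2: (0.015, 0.015), 3: (0.015, 0.015)},
        "sbp": {0: (0.30, 0.30), 1: (0.50, 0.50), 2: (0.70, 0.70), 3: (0.50, 0.50)},
        "total_chol": {0: (0.030, 0.030), 1: (0.020, 0.020), 2: (0.000, 0.000), 3: (-0.020, -0.020)},
    }


@dataclass
class TrajectoryParams:
    """Annual drifts, person-slope SDs, the IGR ramp, and treatment effects.

    Treatment effects are the one-off level reductions applied when the
    corresponding treatment begins: antihypertensives on SBP (mmHg),
    statins on total cholesterol (mmol/L), post-diagnosis diabetes care on
    HbA1c (percent units).  All must be >= 0 (they subtract).
    """

    drift: dict = field(default_factory=_default_drift)
    slope_sd: dict = field(
        default_factory=lambda: {"bmi": 0.05, "hba1c": 0.004, "sbp": 0.20, "total_chol": 0.010}
    )
    igr_acceleration: float = 0.08  # extra HbA1c %/yr while undiagnosed in IGR
    igr_ramp_start: float = 6.0
    treatment_effects: dict = field(
        default_factory=lambda: {"sbp": 10.0, "total_chol": 1.0, "hba1c": 0.5}
    )
    bounds: dict = field(
        default_factory=lambda: {
            "bmi": (15.0, 70.0),
            "sbp": (70.0, 250.0),
            "hba1c": (3.5, 15.0),
            "total_chol": (1.0, 15.0),
        }
    )

    def validate(self) -> None:
        if any(sd < 0 for sd in self.slope_sd.values()):
            raise ValueError("slope_sd values must be >= 0")
        if any(v < 0 for v in self.treatment_effects.values()):
            raise ValueError("treatment_effects must be >= 0 (they subtract)")


def age_band_index(age) -> np.ndarray:
    age = np.asarray(age)
    idx = np.zeros(age.shape, dtype=np.int64)
    for i, (lo, hi) in enumerate(AGE_BANDS):
        idx[(age >= lo) & (age <= hi)] = i
    return idx


def drift_for(params: TrajectoryParams, factor: str, age, sex) -> np.ndarray:
    """Annual drift for each person given current age band and sex."""
    idx = age_band_index(age)
    table = params.drift[factor]
    male = np.array([table[i][0] for i in range(len(AGE_BANDS))])
    female = np.array([table[i][1] for i in range(len(AGE_BANDS))])
    is_female = np.asarray(sex) == "female"
    return np.where(is_female, female[idx], male[idx])


def draw_slopes(n: int, params: TrajectoryParams, rng: np.random.Generator) -> dict:
    """Person-level random slopes, drawn once at baseline."""
    return {f: params.slope_sd[f] * rng.standard_normal(n) for f in FACTORS}


def advance_metabolic(
    state: dict,
    params: TrajectoryParams,
    intervention_delta: dict | None = None,
    treatment_delta: dict | None = None,
) -> dict:
    """Advance all four factors and age by one yearly cycle, in place.

    `state` maps column names to numpy arrays (see engine.state_from_frame);
    all individuals in it must be alive.  `intervention_delta` holds the
    year-on-year change of the (already decayed) intervention effect;
    `treatment_delta` holds this cycle's one-off treatment reductions
    (positive values subtract).
    """
    if not np.all(state["alive"]):
        raise DeadIndividualError("advance_metabolic called on a dead individual")
    intervention_delta = intervention_delta or {}
    treatment_delta = treatment_delta or {}
    age, sex = state["age"], state["sex"]
    slopes = state.get("slopes", {})
    for f in FACTORS:
        d = drift_for(params, f, age, sex).astype(float)
        if f == "hba1c":
            ramp = (
                (state["hba1c"] >= params.igr_ramp_start)
                & (state["hba1c"] < 6.5)
                & ~state["diagnosed_diabetes"]
            )
            d = d + params.igr_acceleration * ramp
        new = (
            state[f]
            + d
            + slopes.get(f, 0.0)
            + np.asarray(intervention_delta.get(f, 0.0))
            - np.asarray(treatment_delta.get(f, 0.0))
        )
        lo, hi = params.bounds[f]
        state[f] = np.clip(new, lo, hi)
    state["age"] = age + 1
    return state


def hba1c_phase(hba1c, diagnosed, igr_threshold: float = 6.0, diabetes_threshold: float = 6.5):
    """Classify glycaemic phase: normo / igr / undiagnosed_diabetes / diagnosed_diabetes.

    A diabetes diagnosis is sticky: diagnosed individuals stay in the
    diagnosed phase even if treatment brings HbA1c back under threshold.
    """
    hba1c = np.atleast_1d(np.asarray(hba1c, dtype=float))
    diagnosed = np.atleast_1d(np.asarray(diagnosed, dtype=bool))
    out = np.full(hba1c.shape, "normo", dtype=object)
    out[(hba1c >= igr_threshold) & (hba1c < diabetes_threshold)] = "igr"
    out[hba1c >= diabetes_threshold] = "undiagnosed_diabetes"
    out[diagnosed] = "diagnosed_diabetes"
    return out if out.size > 1 else out[0]
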