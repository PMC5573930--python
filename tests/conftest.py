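import copy

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prevsim import care_events, engine, synthpop, trajectories


def make_state(n=1, **overrides):
    """A minimal simulation state of n identical individuals."""
    base = dict(
        id=0, age=50, sex="male", ethnicity="white", imd_quintile=3,
        employed=False, bmi=27.0, hba1c=5.4, sbp=125.0, total_chol=5.2,
        hdl_chol=1.4, smoker="non", family_history_diabetes=False,
        eq5d_baseline=0.9,
    )
    base.update(overrides)
    rows = []
    for i in range(n):
        row = dict(base)
        row["id"] = i
        rows.append(synthpop.Individual(**row).to_row())
    df = pd.DataFrame(rows)
    df["diabetes_onset_year"] = df["diabetes_onset_year"].astype("Int64")
    df = df[list(synthpop.COLUMNS)]
    state = engine.state_from_frame(df)
    state["employed_now"] = state["employed"] & state["alive"]
    return state


def zero_drift_params(**kw):
    """TrajectoryParams with every drift, slope and ramp zeroed."""
    drift = {f: {i: (0.0, 0.0) for i in range(4)} for f in trajectories.FACTORS}
    slope_sd = {f: 0.0 for f in trajectories.FACTORS}
    defaults = dict(drift=drift, slope_sd=slope_sd, igr_acceleration=0.0)
    defaults.update(kw)
    return trajectories.TrajectoryParams(**defaults)


def zero_hazard_equations(**overrides):
    """A RiskEquationSet with every hazard switched off; overrides are
    applied on top (e.g. {'cvd.h0': 0.02})."""
    eqs = care_events.RiskEquationSet()
    c = copy.deepcopy(eqs.coeffs)
    for name in ("cvd", "chf", "breast_cancer", "colon_cancer",
                 "osteoarthritis", "depression"):
        c[name]["h0"] = 0.0
    for comp in c["microvascular"]["base"]:
        c["microvascular"]["base"][comp] = 0.0
    for sex in ("male", "female"):
        c["mortality"]["makeham"][sex] = 0.0
        c["mortality"]["a"][sex] = 0.0
    c["mortality"]["cvd_case_fatality"] = 0.0
    c["mortality"]["cancer_death"]["breast_cancer"] = 0.0
    c["mortality"]["cancer_death"]["colon_cancer"] = 0.0
    for path, val in overrides.items():
        node = c
        *head, leaf = path.split(".")
        for k in head:
            node = node[k]
        node[leaf] = val
    return care_events.RiskEquationSet(coeffs=c)


def binom_ci99(n, p):
    """Two-sided 99% binomial acceptance interval for a count."""
    lo = stats.binom.ppf(0.005, n, p)
    hi = stats.binom.ppf(0.995, n, p)
    return lo, hi


@pytest.fixture(scope="session")
def small_cohort():
    return synthpop.generate_population(synthpop.PopulationSpec(n=2000, seed=11))


@pytest.fixture(scope="session")
def quiet_cfg():
    """A fast scenario config: small cohort, short horizon."""
    return engine.ScenarioConfig(
        population=synthpop.PopulationSpec(n=2000), seed=11, max_cycles=15
    )
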