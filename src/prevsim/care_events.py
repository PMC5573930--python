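"""Yearly GP visit, diabetes screening cascade, and competing health events.

Each simulated year, people visit their GP and may be diagnosed with
diabetes, hypertension or dyslipidaemia and treated accordingly.  Under the
high-risk intervention a one-off screening cascade runs: a diabetes risk
score selects people for invitation, attenders get an HbA1c test (charged
to the NHS), test results either diagnose diabetes or, in the impaired-
glucose-regulation (IGR) band, trigger an offer of the lifestyle programme.

The annual event step samples, per person, cardiovascular disease, heart
failure, the four microvascular complications of diabetes, breast and
colon cancer, osteoarthritis, depression, and death (CVD case fatality,
cancer-specific, and all-cause other causes, resolved in a fixed order).
Event probabilities come from a swappable RiskEquationSet whose shipped
coefficients live in a JSON resource; every equation is monotone
non-decreasing in its adverse exposures by construction (positive
log-hazard coefficients).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import numpy as np

from . import rng as crn

__all__ = [
    "GPConfig",
    "ScreeningConfig",
    "RiskEquationSet",
    "ProbabilityError",
    "MissingFieldError",
    "gp_visit",
    "risk_score",
    "load_score_table",
    "screening_cascade",
    "annual_events",
    "EVENT_ORDER",
    "DEATH_ORDER",
]

# Fixed sampling order for the ledger; death causes resolved afterwards in
# DEATH_ORDER (first matching cause wins).
EVENT_ORDER = (
    "cvd",
    "chf",
    "foot_ulcer",
    "amputation",
    "blindness",
    "renal_failure",
    "breast_cancer",
    "colon_cancer",
    "osteoarthritis",
    "depression",
)
DEATH_ORDER = ("death_cvd", "death_cancer", "death_other")


class ProbabilityError(ValueError):
    """A risk equation returned a probability outside [0, 1]."""


class MissingFieldError(KeyError):
    """A required individual field is absent."""


def _resource_json(name: str) -> dict:
    with importlib_resources.files("prevsim.resources").joinpath(name).open() as fh:
        return json.load(fh)


@dataclass
class GPConfig:
    """Thresholds and annual detection probabilities for the GP visit."""

    diabetes_threshold: float = 6.5  # HbA1c %, DCCT
    diabetes_detection_p: float = 0.10  # symptomatic detection per year
    htn_threshold: float = 140.0  # mmHg
    htn_detection_p: float = 0.8
    dyslip_threshold: float = 5.0  # mmol/L total cholesterol
    dyslip_detection_p: float = 0.8


@dataclass
class ScreeningConfig:
    """One-off vascular-check screening cascade parameters."""

    vascular_check_attendance: float = 0.437
    risk_score_threshold: float = 4.75
    screen_test_cost: float = 14.0  # GBP per HbA1c test, charged to the NHS
    igr_threshold: float = 6.0  # HbA1c %
    diabetes_threshold: float = 6.5  # HbA1c %
    programme_uptake: float = 0.32

    def validate(self) -> None:
        for name in ("vascular_check_attendance", "programme_uptake"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}: must lie in [0, 1]")
        if not self.igr_threshold < self.diabetes_threshold:
            raise ValueError("igr_threshold must be below diabetes_threshold")


def gp_visit(state: dict, cfg: GPConfig, cycle: int, seed: int, draws: dict | None = None) -> dict:
    """Diagnose and initiate treatment at the yearly GP visit, in place.

    Returns masks of this cycle's *new* diagnoses so the engine can apply
    one-off treatment effects in the next trajectory update.  Dead
    individuals are never diagnosed.
    """
    n = state["age"].shape[0]
    alive = state["alive"]
    if draws is None:
        draws = {
            ch: crn.uniforms(seed, ch, cycle, n)
            for ch in ("gp_diabetes", "gp_hypertension", "gp_dyslipidaemia")
        }

    new_dm = (
        alive
        & ~state["diagnosed_diabetes"]
        & (state["hba1c"] >= cfg.diabetes_threshold)
        & (draws["gp_diabetes"] < cfg.diabetes_detection_p)
    )
    state["diagnosed_diabetes"] |= new_dm
    unset = np.isnan(state["diabetes_onset_year"])
    state["diabetes_onset_year"] = np.where(
        new_dm & unset, float(cycle), state["diabetes_onset_year"]
    )

    new_htn = (
        alive
        & ~state["diagnosed_hypertension"]
        & (state["sbp"] >= cfg.htn_threshold)
        & (draws["gp_hypertension"] < cfg.htn_detection_p)
    )
    state["diagnosed_hypertension"] |= new_htn

    new_dys = (
        alive
        & ~state["diagnosed_dyslipidaemia"]
        & (state["total_chol"] >= cfg.dyslip_threshold)
        & (draws["gp_dyslipidaemia"] < cfg.dyslip_detection_p)
    )
    state["diagnosed_dyslipidaemia"] |= new_dys

    return {"diabetes": new_dm, "hypertension": new_htn, "dyslipidaemia": new_dys}


def load_score_table(path=None) -> dict:
    """Diabetes risk-score coefficient table (shipped default or user JSON)."""
    if path is None:
        return _resource_json("leicester_score.json")
    with open(path) as fh:
        return json.load(fh)


def risk_score(state: dict, table: dict | None = None) -> np.ndarray:
    """Additive diabetes risk score (Leicester-style), deterministic.

    Monotone in age band and BMI band; raises MissingFieldError naming any
    absent field.
    """
    table = table or load_score_table()
    for f in ("age", "sex", "ethnicity", "family_history_diabetes", "bmi",
              "diagnosed_hypertension"):
        if f not in state:
            raise MissingFieldError(f)
    n = state["age"].shape[0]
    score = np.zeros(n)
    for lo, hi, pts in table["age_bands"]:
        score += pts * ((state["age"] >= lo) & (state["age"] <= hi))
    for lo, hi, pts in table["bmi_bands"]:
        score += pts * ((state["bmi"] >= lo) & (state["bmi"] < hi))
    sex_pts = np.where(state["sex"] == "male", table["sex"]["male"], table["sex"]["female"])
    score += sex_pts
    eth = np.zeros(n)
    for name, pts in table["ethnicity"].items():
        eth += pts * (state["ethnicity"] == name)
    score += eth
    score += table["family_history"] * state["family_history_diabetes"]
    score += table["antihypertensive"] * state["diagnosed_hypertension"]
    return score


def screening_cascade(
    state: dict,
    cfg: ScreeningConfig,
    seed: int,
    cycle: int = 0,
    score_table: dict | None = None,
    scores: np.ndarray | None = None,
) -> dict:
    """Run the one-off screening cascade, in place.

    Invitation requires risk score above threshold; attendance is
    Bernoulli(vascular_check_attendance); attenders above threshold get an
    HbA1c test charged to the NHS; test >= diabetes threshold diagnoses
    diabetes, the IGR band triggers a programme offer accepted with
    probability programme_uptake.  Returns disjoint masks and the per-person
    NHS cost of the tests.
    """
    cfg.validate()
    n = state["age"].shape[0]
    alive = state["alive"]
    if scores is None:
        scores = risk_score(state, score_table)

    u_att = crn.uniforms(seed, "screen_attend", cycle, n)
    u_upt = crn.uniforms(seed, "screen_uptake", cycle, n)

    eligible = alive & ~state["diagnosed_diabetes"]
    attended = eligible & (u_att < cfg.vascular_check_attendance)
    tested = attended & (scores > cfg.risk_score_threshold)
    diagnosed = tested & (state["hba1c"] >= cfg.diabetes_threshold)
    igr = tested & (state["hba1c"] >= cfg.igr_threshold) & ~diagnosed
    accepted = igr & (u_upt < cfg.programme_uptake)

    state["diagnosed_diabetes"] |= diagnosed
    unset = np.isnan(state["diabetes_onset_year"])
    state["diabetes_onset_year"] = np.where(
        diagnosed & unset, float(cycle), state["diabetes_onset_year"]
    )

    cost = np.where(tested, cfg.screen_test_cost, 0.0)
    return {
        "attended": attended,
        "tested": tested,
        "diagnosed_diabetes": diagnosed,
        "igr_offered": igr,
        "accepted": accepted,
        "nhs_cost": cost,
    }


@dataclass
class RiskEquationSet:
    """Annual event-probability equations behind a swappable coefficient set.

    Hazards are h0 * exp(linear predictor); probabilities 1 - exp(-h).
    Positive coefficients on the adverse exposures make every equation
    monotone non-decreasing in HbA1c, SBP, BMI and age.
    """

    coeffs: dict = field(default_factory=lambda: _resource_json("risk_equations.json"))
    depression_trigger: str = "diagnosis"  # or "onset" (Table-3b-style switch)

    @classmethod
    def from_json(cls, path) -> "RiskEquationSet":
        with open(path) as fh:
            return cls(coeffs=json.load(fh))

    # -- helpers -------------------------------------------------------
    @staticmethod
    def _p(hazard: np.ndarray) -> np.ndarray:
        return 1.0 - np.exp(-np.maximum(hazard, 0.0))

    @staticmethod
    def _diabetes_any(state: dict) -> np.ndarray:
        return state["diagnosed_diabetes"] | ~np.isnan(state["diabetes_onset_year"])

    # -- equations -----------------------------------------------------
    def p_cvd(self, state: dict) -> np.ndarray:
        c = self.coeffs["cvd"]
        ratio = state["total_chol"] / state["hdl_chol"]
        lp = (
            c["age"] * (state["age"] - c["age_ref"])
            + c["male"] * (state["sex"] == "male")
            + c["sbp"] * (state["sbp"] - c["sbp_ref"])
            + c["ratio"] * (ratio - c["ratio_ref"])
            + c["smoker_ex"] * (state["smoker"] == "ex")
            + c["smoker_current"] * (state["smoker"] == "current")
            + c["bmi"] * (state["bmi"] - c["bmi_ref"])
            + c["diabetes"] * self._diabetes_any(state)
            + c["imd"] * (state["imd_quintile"] - c["imd_ref"])
        )
        return self._p(c["h0"] * np.exp(lp))

    def p_chf(self, state: dict) -> np.ndarray:
        c = self.coeffs["chf"]
        lp = (
            c["age"] * (state["age"] - c["age_ref"])
            + c["male"] * (state["sex"] == "male")
            + c["sbp"] * (state["sbp"] - c["sbp_ref"])
            + c["bmi"] * (state["bmi"] - c["bmi_ref"])
            + c["diabetes"] * self._diabetes_any(state)
            + c["cvd"] * state["has_cvd"]
        )
        return self._p(c["h0"] * np.exp(lp))

    def p_microvascular(self, state: dict, complication: str, cycle: int) -> np.ndarray:
        """UKPDS-style complication hazard; requires diabetes (diagnosed or not)."""
        c = self.coeffs["microvascular"]
        dm = self._diabetes_any(state)
        duration = np.where(
            np.isnan(state["diabetes_onset_year"]),
            0.0,
            np.maximum(cycle - state["diabetes_onset_year"], 0.0),
        )
        lp = c["hba1c"] * (state["hba1c"] - c["hba1c_ref"]) + c["duration"] * duration
        return np.where(dm, self._p(c["base"][complication] * np.exp(lp)), 0.0)

    def p_breast_cancer(self, state: dict) -> np.ndarray:
        c = self.coeffs["breast_cancer"]
        lp = c["age"] * (state["age"] - c["age_ref"]) + c["bmi"] * (state["bmi"] - c["bmi_ref"])
        return np.where(state["sex"] == "female", self._p(c["h0"] * np.exp(lp)), 0.0)

    def p_colon_cancer(self, state: dict) -> np.ndarray:
        c = self.coeffs["colon_cancer"]
        lp = c["age"] * (state["age"] - c["age_ref"]) + c["bmi"] * (state["bmi"] - c["bmi_ref"])
        return self._p(c["h0"] * np.exp(lp))

    def p_osteoarthritis(self, state: dict) -> np.ndarray:
        c = self.coeffs["osteoarthritis"]
        lp = c["age"] * (state["age"] - c["age_ref"]) + c["bmi"] * (state["bmi"] - c["bmi_ref"])
        return self._p(c["h0"] * np.exp(lp))

    def p_depression(self, state: dict) -> np.ndarray:
        c = self.coeffs["depression"]
        if self.depression_trigger == "onset":
            dm = self._diabetes_any(state)
        else:
            dm = state["diagnosed_diabetes"]
        return self._p(c["h0"] * np.where(dm, c["rr_diabetes"], 1.0))

    def p_other_death(self, state: dict) -> np.ndarray:
        """All-cause (non-CVD-event, non-cancer) mortality: Gompertz-Makeham
        life-table hazard by age/sex times condition relative risks."""
        m = self.coeffs["mortality"]
        male = state["sex"] == "male"
        a = np.where(male, m["a"]["male"], m["a"]["female"])
        b = np.where(male, m["b"]["male"], m["b"]["female"])
        mk = np.where(male, m["makeham"]["male"], m["makeham"]["female"])
        h = mk + a * np.exp(b * state["age"])
        lp = np.zeros(state["age"].shape)
        lp += m["log_rr"]["diabetes"] * self._diabetes_any(state)
        for cond, lr in m["log_rr"].items():
            if cond == "diabetes":
                continue
            lp += lr * state[f"has_{cond}"]
        return self._p(h * np.exp(lp))

    def probabilities(self, state: dict, cycle: int) -> dict:
        p = {
            "cvd": self.p_cvd(state),
            "chf": self.p_chf(state),
            "foot_ulcer": self.p_microvascular(state, "foot_ulcer", cycle),
            "amputation": self.p_microvascular(state, "amputation", cycle),
            "blindness": self.p_microvascular(state, "blindness", cycle),
            "renal_failure": self.p_microvascular(state, "renal_failure", cycle),
            "breast_cancer": self.p_breast_cancer(state),
            "colon_cancer": self.p_colon_cancer(state),
            "osteoarthritis": self.p_osteoarthritis(state),
            "depression": self.p_depression(state),
        }
        return p


def annual_events(
    state: dict,
    eqs: RiskEquationSet,
    cycle: int,
    seed: int,
    draws: dict | None = None,
) -> dict:
    """Sample this cycle's events and deaths, updating flags in place.

    Returns {event name: fired mask} including the three death causes
    (mutually exclusive, resolved CVD > cancer > other).  Dead individuals
    fire nothing.  Raises ProbabilityError if a (user-supplied) equation
    returns a probability outside [0, 1].
    """
    n = state["age"].shape[0]
    alive = state["alive"]
    probs = eqs.probabilities(state, cycle)
    for name, p in probs.items():
        if np.any(p < 0) or np.any(p > 1):
            raise ProbabilityError(f"equation '{name}' returned probability outside [0, 1]")

    if draws is None:
        chans = list(EVENT_ORDER) + ["cvd_fatal", "cancer_death", "other_death"]
        draws = {ch: crn.uniforms(seed, ch, cycle, n) for ch in chans}

    events: dict[str, np.ndarray] = {}
    for name in EVENT_ORDER:
        fired = alive & ~state[f"has_{name}"] & (draws[name] < probs[name])
        state[f"has_{name}"] |= fired
        events[name] = fired

    m = eqs.coeffs["mortality"]
    cf = m["cvd_case_fatality"]
    if not 0.0 <= cf <= 1.0:
        raise ProbabilityError("cvd_case_fatality outside [0, 1]")
    death_cvd = events["cvd"] & (draws["cvd_fatal"] < cf)

    h_cancer = (
        m["cancer_death"]["breast_cancer"] * state["has_breast_cancer"]
        + m["cancer_death"]["colon_cancer"] * state["has_colon_cancer"]
    )
    p_cancer = 1.0 - np.exp(-h_cancer)
    death_cancer = alive & (draws["cancer_death"] < p_cancer)

    p_other = eqs.p_other_death(state)
    if np.any(p_other < 0) or np.any(p_other > 1):
        raise ProbabilityError("mortality equation returned probability outside [0, 1]")
    death_other = alive & (draws["other_death"] < p_other)

    # fixed cause resolution order
    death_cancer &= ~death_cvd
    death_other &= ~death_cvd & ~death_cancer
    events["death_cvd"] = death_cvd
    events["death_cancer"] = death_cancer
    events["death_other"] = death_other
    state["alive"] = alive & ~(death_cvd | death_cancer | death_other)
    return events
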