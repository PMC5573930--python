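import numpy as np
import pytest

from conftest import binom_ci99, make_state, zero_hazard_equations
from prevsim import care_events
from prevsim.care_events import (
    GPConfig,
    MissingFieldError,
    ProbabilityError,
    RiskEquationSet,
    ScreeningConfig,
    annual_events,
    gp_visit,
    risk_score,
    screening_cascade,
)


class TestGPVisit:
    def test_certain_detection_diagnoses_and_sets_onset(self):
        state = make_state(hba1c=7.2)
        new = gp_visit(state, GPConfig(diabetes_detection_p=1.0), cycle=3, seed=1)
        assert new["diabetes"][0]
        assert state["diagnosed_diabetes"][0]
        assert state["diabetes_onset_year"][0] == 3.0

    def test_below_thresholds_no_diagnoses(self):
        state = make_state(hba1c=5.0, sbp=120.0, total_chol=4.0)
        new = gp_visit(state, GPConfig(diabetes_detection_p=1.0, htn_detection_p=1.0,
                                       dyslip_detection_p=1.0), cycle=0, seed=1)
        assert not any(m.any() for m in new.values())

    def test_detection_probability_binomial(self):
        n = 10_000
        state = make_state(n=n, hba1c=7.0)
        new = gp_visit(state, GPConfig(diabetes_detection_p=0.3), cycle=0, seed=5)
        lo, hi = binom_ci99(n, 0.3)
        assert lo <= new["diabetes"].sum() <= hi

    def test_dead_are_never_diagnosed(self):
        state = make_state(n=4, hba1c=8.0)
        state["alive"][:] = False
        new = gp_visit(state, GPConfig(diabetes_detection_p=1.0), cycle=0, seed=1)
        assert not new["diabetes"].any()


class TestRiskScore:
    def test_monotone_in_bmi(self):
        lo = risk_score(make_state(bmi=24.0))
        hi = risk_score(make_state(bmi=36.0))
        assert hi[0] > lo[0]

    def test_minimum_risk_profile_scores_minimum(self):
        state = make_state(age=20, sex="female", bmi=22.0)
        assert risk_score(state)[0] == 0.0

    def test_missing_field_named(self):
        state = make_state()
        del state["bmi"]
        with pytest.raises(MissingFieldError, match="bmi"):
            risk_score(state)

    def test_threshold_separates_invitation_outcomes(self):
        # high-risk profile above 4.75 gets tested; low-risk does not
        cfg = ScreeningConfig(vascular_check_attendance=1.0)
        high = make_state(age=60, bmi=36.0, family_history_diabetes=True, hba1c=5.5)
        low = make_state(age=20, sex="female", bmi=22.0, hba1c=5.5)
        assert risk_score(high)[0] > 4.75
        assert risk_score(low)[0] < 4.75
        assert screening_cascade(high, cfg, seed=1)["tested"][0]
        assert not screening_cascade(low, cfg, seed=1)["tested"][0]


class TestScreeningCascade:
    def test_attendance_binomial(self):
        n = 10_000
        state = make_state(n=n, age=60, bmi=36.0, family_history_diabetes=True)
        out = screening_cascade(state, ScreeningConfig(), seed=2)
        lo, hi = binom_ci99(n, 0.437)
        assert lo <= out["attended"].sum() <= hi

    def test_zero_attendance_degenerate(self):
        state = make_state(n=100, age=60, bmi=36.0)
        out = screening_cascade(state, ScreeningConfig(vascular_check_attendance=0.0), seed=2)
        assert not out["attended"].any()
        assert out["nhs_cost"].sum() == 0.0

    def test_igr_uptake_binomial(self):
        n = 10_000
        state = make_state(n=n, age=60, bmi=36.0, hba1c=6.2)
        out = screening_cascade(
            state, ScreeningConfig(vascular_check_attendance=1.0), seed=3
        )
        assert out["igr_offered"].sum() == n
        lo, hi = binom_ci99(n, 0.32)
        assert lo <= out["accepted"].sum() <= hi

    def test_screen_detects_diabetes_and_charges_tests(self):
        state = make_state(n=50, age=60, bmi=36.0, hba1c=7.0)
        out = screening_cascade(
            state, ScreeningConfig(vascular_check_attendance=1.0), seed=4
        )
        assert out["diagnosed_diabetes"].sum() == 50
        assert state["diagnosed_diabetes"].all()
        assert out["nhs_cost"].sum() == pytest.approx(50 * 14.0)

    def test_cascade_partition_conservation(self):
        state = make_state(n=5000, age=60, bmi=36.0)
        # spread HbA1c across the three bands
        state["hba1c"] = np.linspace(5.0, 7.5, 5000)
        out = screening_cascade(state, ScreeningConfig(), seed=5)
        dx, igr = out["diagnosed_diabetes"], out["igr_offered"]
        negative = out["attended"] & ~dx & ~igr
        assert not (dx & igr).any()
        assert not (dx & negative).any()
        assert not (igr & negative).any()
        assert np.array_equal(dx | igr | negative, out["attended"])


class TestAnnualEvents:
    def test_zero_hazards_nothing_happens(self):
        state = make_state(n=20, hba1c=8.0)
        events = annual_events(state, zero_hazard_equations(), cycle=0, seed=1)
        assert not any(m.any() for m in events.values())
        assert state["alive"].all()

    def test_certain_mortality_cause_other(self):
        eqs = zero_hazard_equations(**{"mortality.makeham.male": 1e9,
                                       "mortality.makeham.female": 1e9})
        state = make_state(n=5)
        events = annual_events(state, eqs, cycle=0, seed=1)
        assert events["death_other"].all()
        assert not events["death_cvd"].any()
        assert not state["alive"].any()

    def test_cvd_binomial_oracle(self):
        # flat 2% annual CVD probability: h0 = -ln(0.98), covariates off
        n = 100_000
        eqs = zero_hazard_equations()
        c = eqs.coeffs["cvd"]
        c.update({"h0": -np.log(0.98), "age": 0.0, "male": 0.0, "sbp": 0.0,
                  "ratio": 0.0, "smoker_ex": 0.0, "smoker_current": 0.0,
                  "bmi": 0.0, "diabetes": 0.0, "imd": 0.0})
        state = make_state(n=n)
        events = annual_events(state, eqs, cycle=0, seed=9)
        lo, hi = binom_ci99(n, 0.02)
        assert lo <= events["cvd"].sum() <= hi

    def test_dead_fire_no_events_and_cause_resolution_order(self):
        state = make_state(n=10)
        state["alive"][:] = False
        eqs = zero_hazard_equations(**{"mortality.makeham.male": 1e9})
        events = annual_events(state, eqs, cycle=0, seed=1)
        assert not any(m.any() for m in events.values())

    def test_invalid_user_probability_rejected(self):
        class Bad(RiskEquationSet):
            def p_cvd(self, state):
                return np.full(state["age"].shape, 1.5)

        with pytest.raises(ProbabilityError, match="cvd"):
            annual_events(make_state(), Bad(), cycle=0, seed=1)

    def test_microvascular_requires_diabetes(self):
        eqs = RiskEquationSet()
        no_dm = make_state(hba1c=5.5)
        dm = make_state(hba1c=8.0, diagnosed_diabetes=True, diabetes_onset_year=0)
        assert eqs.p_microvascular(no_dm, "blindness", cycle=5)[0] == 0.0
        assert eqs.p_microvascular(dm, "blindness", cycle=5)[0] > 0.0


class TestMonotonicity:
    """Each risk equation is weakly increasing in its adverse exposure."""

    GRID = np.linspace(0, 1, 6)

    def _sorted(self, vals):
        vals = np.asarray(vals)
        return np.all(np.diff(vals) >= 0)

    def test_microvascular_in_hba1c(self):
        eqs = RiskEquationSet()
        ps = [
            eqs.p_microvascular(
                make_state(hba1c=h, diagnosed_diabetes=True, diabetes_onset_year=0),
                "foot_ulcer", cycle=3,
            )[0]
            for h in np.linspace(6.5, 11.0, 8)
        ]
        assert self._sorted(ps)

    def test_cvd_in_sbp_and_bmi_and_age(self):
        eqs = RiskEquationSet()
        for field, grid in (("sbp", np.linspace(100, 200, 8)),
                            ("bmi", np.linspace(18, 45, 8)),
                            ("age", np.arange(20, 100, 10))):
            ps = [eqs.p_cvd(make_state(**{field: x}))[0] for x in grid]
            assert self._sorted(ps), field

    def test_osteoarthritis_in_bmi(self):
        eqs = RiskEquationSet()
        ps = [eqs.p_osteoarthritis(make_state(bmi=b))[0] for b in np.linspace(18, 50, 8)]
        assert self._sorted(ps)

    def test_chf_in_sbp(self):
        eqs = RiskEquationSet()
        ps = [eqs.p_chf(make_state(sbp=s))[0] for s in np.linspace(100, 200, 8)]
        assert self._sorted(ps)

    def test_mortality_in_age(self):
        eqs = RiskEquationSet()
        ps = [eqs.p_other_death(make_state(age=a))[0] for a in np.arange(20, 110, 10)]
        assert self._sorted(ps)

    def test_all_probabilities_in_unit_interval(self):
        eqs = RiskEquationSet()
        state = make_state(n=64, age=95, bmi=60.0, sbp=240.0, hba1c=14.0,
                           diagnosed_diabetes=True, diabetes_onset_year=0)
        for name, p in eqs.probabilities(state, cycle=40).items():
            assert np.all((p >= 0) & (p <= 1)), name


def test_depression_trigger_switch():
    diag = make_state(diagnosed_diabetes=True, diabetes_onset_year=0)
    onset_only = make_state(hba1c=7.0, diabetes_onset_year=0)
    base = RiskEquationSet(depression_trigger="diagnosis")
    sens = RiskEquationSet(depression_trigger="onset")
    assert base.p_depression(diag)[0] > base.p_depression(onset_only)[0]
    assert sens.p_depression(onset_only)[0] == sens.p_depression(diag)[0]
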