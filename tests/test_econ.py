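import copy

import numpy as np
import pandas as pd
import pytest

from conftest import make_state
from prevsim import econ
from prevsim.econ import (
    EconConfig,
    FrictionConfig,
    Ledger,
    aggregate,
    annual_absence,
    annual_cost,
    annual_utility,
    discount,
    discount_factors,
    incremental_net_benefit,
    load_cost_table,
)


@pytest.fixture
def table():
    return load_cost_table()


class TestAnnualCost:
    def test_healthy_person_costs_nothing(self, table):
        assert annual_cost(make_state(), table)[0] == 0.0

    def test_diabetes_annual_cost(self, table):
        t = copy.deepcopy(table)
        t["diabetes"]["annual_cost"] = 300.0
        state = make_state(diagnosed_diabetes=True)
        assert annual_cost(state, t)[0] == 300.0

    def test_event_cost_adds_to_annual(self, table):
        # diabetic with a CVD event this cycle: diabetes annual + CVD event
        state = make_state(diagnosed_diabetes=True)
        events = {"cvd": np.array([True])}
        expected = table["diabetes"]["annual_cost"] + table["cvd"]["event_cost"]
        assert annual_cost(state, table, events)[0] == expected

    def test_treatment_costs_added(self, table):
        state = make_state(diagnosed_hypertension=True, diagnosed_dyslipidaemia=True)
        got = annual_cost(state, table, treatment_costs={"antihypertensive": 30.0,
                                                         "statin": 25.0})[0]
        assert got == 55.0

    def test_missing_condition_named(self, table):
        t = {k: v for k, v in table.items() if k != "renal_failure"}
        with pytest.raises(KeyError, match="renal_failure"):
            annual_cost(make_state(), t)

    def test_dead_cost_nothing(self, table):
        state = make_state(diagnosed_diabetes=True)
        state["alive"][:] = False
        assert annual_cost(state, table)[0] == 0.0


class TestAnnualUtility:
    def test_baseline_identity(self):
        cfg = EconConfig(age_decrement_rate=0.0)
        assert annual_utility(make_state(eq5d_baseline=0.9), cfg)[0] == pytest.approx(0.9)

    def test_dead_is_zero(self):
        state = make_state(eq5d_baseline=0.9)
        state["alive"][:] = False
        assert annual_utility(state, EconConfig())[0] == 0.0

    def test_additive_decrements(self, table):
        t = copy.deepcopy(table)
        t["cvd"]["utility_decrement"] = 0.10
        t["depression"]["utility_decrement"] = 0.15
        cfg = EconConfig(cost_table=t, age_decrement_rate=0.0)
        state = make_state(eq5d_baseline=0.9,
                           condition_flags=frozenset({"cvd", "depression"}))
        assert annual_utility(state, cfg)[0] == pytest.approx(0.65)

    def test_floor_applies(self, table):
        t = copy.deepcopy(table)
        t["renal_failure"]["utility_decrement"] = 5.0
        cfg = EconConfig(cost_table=t)
        state = make_state(condition_flags=frozenset({"renal_failure"}))
        assert annual_utility(state, cfg)[0] == cfg.utility_floor


class TestDiscounting:
    def test_year_zero_undiscounted(self):
        assert discount(100.0, 0, 0.015) == 100.0

    def test_first_year_closed_form(self):
        assert discount(100.0, 1, 0.015) == pytest.approx(100.0 / 1.015)

    def test_zero_rate_identity(self):
        assert discount(123.4, 17, 0.0) == 123.4

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount(1.0, 0, -0.01)

    def test_constant_stream_geometric_sum(self):
        rate, T, c = 0.015, 40, 7.5
        total = (c * discount_factors(T, rate)).sum()
        f = 1.0 / (1.0 + rate)
        assert total == pytest.approx(c * (1 - f**T) / (1 - f))


class TestNetBenefit:
    def test_zero_case(self):
        assert incremental_net_benefit(0.0, 0.0, 20_000) == 0.0

    def test_linearity_in_lambda(self):
        dq, dc = 0.002, -5.0
        nb1 = incremental_net_benefit(dq, dc, 10_000)
        nb2 = incremental_net_benefit(dq, dc, 30_000)
        assert nb2 - nb1 == pytest.approx(20_000 * dq)


def _hand_ledgers():
    """3-person, 3-cycle ledgers with hand-computable deltas."""
    cost_0 = np.array([[10.0, 10, 10], [0, 0, 0], [5, 0, 0]])
    cost_i = np.array([[8.0, 10, 10], [0, 0, 0], [5, 0, 0]])
    util_0 = np.array([[0.9, 0.90, 0.9], [0.8, 0.8, 0.8], [0.7, 0, 0]])
    util_i = np.array([[0.9, 0.95, 0.9], [0.8, 0.8, 0.8], [0.7, 0, 0]])
    zeros = np.zeros((3, 3))
    ids = np.arange(3)
    employed = np.array([True, False, False])

    def led(cost, util, absence, deaths):
        return Ledger(
            cost=cost, utility=util, absence_days=absence,
            death_in_employment=deaths,
            events={"cvd": np.zeros((3, 3), dtype=bool)},
            cohort_ids=ids, baseline_employed=employed,
        )

    led_0 = led(cost_0, util_0, zeros.copy(), np.zeros((3, 3), dtype=bool))
    deaths_i = np.zeros((3, 3), dtype=bool)
    deaths_i[0, 2] = True
    absence_i = np.zeros((3, 3))
    absence_i[0, 0] = 1.0
    led_i = led(cost_i, util_i, absence_i, deaths_i)
    return led_i, led_0


def test_aggregate_hand_worked_oracle():
    led_i, led_0 = _hand_ledgers()
    cohort = pd.DataFrame({"imd_quintile": [5, 1, 5]})
    cfg = EconConfig(discount_rate=0.0, horizons=(2, None))
    res = aggregate(led_i, led_0, cohort, cfg)
    # person 0: dQ +0.05 (cycle 1), dC -2 (cycle 0); others zero
    assert res.d_qaly == pytest.approx(0.05 / 3)
    assert res.d_cost == pytest.approx(-2.0 / 3)
    assert res.net_benefit == pytest.approx((20_000 * 0.05 + 2.0) / 3)
    assert res.by_horizon["2y"]["d_qaly"] == pytest.approx(0.05 / 3)
    # employer: 1 extra absence day at £90 + 1 death at £3000, 1 employed
    assert res.employer["cost_per_employed"] == pytest.approx(90.0 + 3000.0)
    assert res.employer["deaths_in_employment_per_5m"] == pytest.approx(5e6 / 3)


def test_aggregate_identity_and_partition():
    led_i, led_0 = _hand_ledgers()
    cohort = pd.DataFrame({"imd_quintile": [5, 1, 5]})
    cfg = EconConfig(horizons=(2, None))
    res = aggregate(led_i, led_0, cohort, cfg)
    # net-benefit identity, every horizon
    for h in res.by_horizon.values():
        assert h["net_benefit"] == pytest.approx(
            cfg.lambda_wtp * h["d_qaly"] - h["d_cost"]
        )
    # quintile splits partition the totals exactly
    assert res.by_imd["d_qaly_sum"].sum() == pytest.approx(res.d_qaly * res.n)
    assert res.by_imd["d_cost_sum"].sum() == pytest.approx(res.d_cost * res.n)
    assert res.by_imd["n"].sum() == res.n


def test_aggregate_self_comparison_is_zero():
    led_i, _ = _hand_ledgers()
    cohort = pd.DataFrame({"imd_quintile": [5, 1, 5]})
    res = aggregate(led_i, led_i, cohort, EconConfig())
    assert res.d_qaly == 0.0 and res.d_cost == 0.0 and res.net_benefit == 0.0


def test_aggregate_rejects_mismatched_cohorts():
    led_i, led_0 = _hand_ledgers()
    led_0.cohort_ids = led_0.cohort_ids + 1
    with pytest.raises(ValueError, match="cohort"):
        aggregate(led_i, led_0, pd.DataFrame({"imd_quintile": [5, 1, 5]}), EconConfig())


class TestAbsence:
    def test_nobody_employed_no_absence(self, table):
        cfg = EconConfig()
        state = make_state(diagnosed_diabetes=True, employed=False)
        assert annual_absence(state, cfg, 0)[0] == 0.0

    def test_trigger_switch_moves_absence_earlier(self):
        # diabetes onset without diagnosis: absence only under 'onset' trigger
        state = make_state(employed=True, hba1c=7.0, diabetes_onset_year=0)
        base = EconConfig(friction=FrictionConfig(absence_trigger="diagnosis"))
        sens = EconConfig(friction=FrictionConfig(absence_trigger="onset"))
        assert annual_absence(state, base, 1)[0] == 0.0
        assert annual_absence(state, sens, 1)[0] > 0.0

    def test_friction_period_caps_days(self, table):
        t = copy.deepcopy(table)
        t["depression"]["absence_days_per_year"] = 500.0
        cfg = EconConfig(cost_table=t, friction=FrictionConfig(friction_period_days=90))
        state = make_state(employed=True, condition_flags=frozenset({"depression"}))
        assert annual_absence(state, cfg, 0)[0] == 90.0
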