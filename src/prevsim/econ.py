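"""NHS/PSS costs, QALYs, discounting, net benefit, equity and employer costs.

Costing follows an NHS/Personal-Social-Services perspective in 2014-15
pounds: each modelled health state carries an annual cost, each incident
event a one-off cost, plus ongoing treatment costs, all attributed at the
end of each yearly cycle (no half-cycle correction; a death mid-cycle
contributes neither cost nor QALYs that cycle).  Health is valued by
EQ-5D-based utility: baseline score minus additive condition decrements
and an ageing decrement, floored at the EQ-5D minimum.  Costs and QALYs
are discounted at 1.5% per year and compared between an intervention and
a do-nothing run of the same cohort, yielding the incremental net monetary
benefit  lambda * dQALY - dCost  at a willingness to pay of £20,000/QALY,
at 5-year, 10-year and lifetime horizons, overall and by deprivation
quintile.

Employer impacts are costed by the friction method: condition-related
absence days (capped at the friction period per person-year) valued at a
daily wage while the person is employed, plus a replacement-recruitment
cost when someone dies in employment.  The shipped cost/utility/absence
table is an editable CSV of placeholder values (see docs/methods.md).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources as importlib_resources

import numpy as np
import pandas as pd

from .synthpop import CONDITIONS, EQ5D_FLOOR

__all__ = [
    "EconConfig",
    "FrictionConfig",
    "Ledger",
    "IncrementalResult",
    "load_cost_table",
    "annual_cost",
    "annual_utility",
    "annual_absence",
    "discount",
    "discount_factors",
    "incremental_net_benefit",
    "aggregate",
    "employer_costs",
    "PAPER_POPULATION",
]

PAPER_POPULATION = 5_000_000  # event deltas are reported per this many people

# conditions with an annual/event cost row; "diabetes" keys off the
# diagnosis flag, the rest off their has_* flags
COSTED_CONDITIONS = ("diabetes",) + CONDITIONS


def load_cost_table(path=None) -> dict:
    """Cost/utility/absence table as {condition: {column: value}}."""
    if path is None:
        src = importlib_resources.files("prevsim.resources").joinpath("cost_table.csv").open()
    else:
        src = open(path)
    with src as fh:
        rows = list(csv.DictReader(fh))
    return {
        r["condition"]: {
            "annual_cost": float(r["annual_cost"]),
            "event_cost": float(r["event_cost"]),
            "utility_decrement": float(r["utility_decrement"]),
            "absence_days_per_year": float(r["absence_days_per_year"]),
        }
        for r in rows
    }


@dataclass
class FrictionConfig:
    """Friction-cost productivity parameters (placeholder defaults)."""

    daily_wage: float = 90.0  # GBP per absence day
    friction_period_days: float = 90.0  # cap on absence per person-year
    recruitment_cost: float = 3000.0  # GBP per death in employment
    absence_trigger: str = "diagnosis"  # or "onset": when diabetes absence starts


@dataclass
class EconConfig:
    lambda_wtp: float = 20_000.0  # GBP per QALY
    discount_rate: float = 0.015  # per year
    horizons: tuple = (5, 10, None)  # None = lifetime
    cost_table: dict = field(default_factory=load_cost_table)
    treatment_costs: dict = field(
        default_factory=lambda: {"antihypertensive": 30.0, "statin": 25.0}
    )
    age_decrement_rate: float = 0.002  # utility lost per year aged in-simulation
    utility_floor: float = EQ5D_FLOOR
    friction: FrictionConfig = field(default_factory=FrictionConfig)

    def validate(self) -> None:
        if self.lambda_wtp < 0:
            raise ValueError("lambda_wtp must be >= 0")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if any(v["utility_decrement"] < 0 for v in self.cost_table.values()):
            raise ValueError("utility decrements must be >= 0")
        if self.friction.absence_trigger not in ("diagnosis", "onset"):
            raise ValueError("absence_trigger must be 'diagnosis' or 'onset'")


def _condition_mask(state: dict, condition: str) -> np.ndarray:
    if condition == "diabetes":
        return state["diagnosed_diabetes"]
    return state[f"has_{condition}"]


def annual_cost(
    state: dict,
    cost_table: dict,
    events: dict | None = None,
    treatment_costs: dict | None = None,
    extra_cost: np.ndarray | float = 0.0,
) -> np.ndarray:
    """This cycle's NHS/PSS cost per person: condition annual costs, this
    cycle's event costs, treatment costs, plus any intervention cost.

    Raises KeyError naming any condition absent from the table.  Dead
    individuals cost nothing.
    """
    n = state["age"].shape[0]
    cost = np.zeros(n)
    for cond in COSTED_CONDITIONS:
        if cond not in cost_table:
            raise KeyError(f"condition '{cond}' missing from cost table")
        cost += cost_table[cond]["annual_cost"] * _condition_mask(state, cond)
    if events:
        for name, fired in events.items():
            if name.startswith("death_"):
                continue
            if name not in cost_table:
                raise KeyError(f"condition '{name}' missing from cost table")
            cost += cost_table[name]["event_cost"] * fired
    if treatment_costs:
        cost += treatment_costs.get("antihypertensive", 0.0) * state["diagnosed_hypertension"]
        cost += treatment_costs.get("statin", 0.0) * state["diagnosed_dyslipidaemia"]
    cost = cost + extra_cost
    return np.where(state["alive"], cost, 0.0)


def annual_utility(state: dict, cfg: EconConfig) -> np.ndarray:
    """QALY weight for this cycle: baseline EQ-5D minus ageing and additive
    condition decrements, floored; exactly 0 for the dead.

    The diabetes decrement attaches to the disease state (diagnosed or
    undiagnosed) — it reflects the illness, not the label — whereas the
    diabetes annual *cost* in annual_cost attaches to diagnosis, because
    care is only delivered once the condition is found."""
    table = cfg.cost_table
    u = state["eq5d_baseline"].astype(float).copy()
    u -= cfg.age_decrement_rate * np.maximum(state["age"] - state["baseline_age"], 0)
    for cond in COSTED_CONDITIONS:
        if cond == "diabetes":
            mask = state["diagnosed_diabetes"] | ~np.isnan(state["diabetes_onset_year"])
        else:
            mask = _condition_mask(state, cond)
        u -= table[cond]["utility_decrement"] * mask
    u = np.clip(u, cfg.utility_floor, 1.0)
    return np.where(state["alive"], u, 0.0)


def annual_absence(state: dict, cfg: EconConfig, cycle: int) -> np.ndarray:
    """Condition-related work-absence days this cycle for the employed,
    capped at the friction period.  Diabetes absence keys off diagnosis or
    (under the sensitivity switch) true onset."""
    table = cfg.cost_table
    n = state["age"].shape[0]
    days = np.zeros(n)
    if cfg.friction.absence_trigger == "onset":
        dm = state["diagnosed_diabetes"] | ~np.isnan(state["diabetes_onset_year"])
    else:
        dm = state["diagnosed_diabetes"]
    days += table["diabetes"]["absence_days_per_year"] * dm
    for cond in CONDITIONS:
        days += table[cond]["absence_days_per_year"] * state[f"has_{cond}"]
    days = np.minimum(days, cfg.friction.friction_period_days)
    working = state["alive"] & state["employed_now"]
    return np.where(working, days, 0.0)


def discount(value, year_index, rate: float):
    """Present value of `value` accrued in cycle `year_index` (0 = first
    cycle, undiscounted): value / (1 + rate)^year_index."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    year_index = np.asarray(year_index)
    if np.any(year_index < 0):
        raise ValueError("year_index must be >= 0")
    return np.asarray(value) / (1.0 + rate) ** year_index


def discount_factors(n_cycles: int, rate: float) -> np.ndarray:
    return discount(np.ones(n_cycles), np.arange(n_cycles), rate)


def incremental_net_benefit(d_qaly, d_cost, lambda_wtp) -> float:
    """Net monetary benefit: lambda * dQALY - dCost (exact identity)."""
    return lambda_wtp * np.asarray(d_qaly) - np.asarray(d_cost)


@dataclass
class Ledger:
    """Per-person, per-cycle simulation ledger (undiscounted)."""

    cost: np.ndarray  # (n, T) GBP
    utility: np.ndarray  # (n, T) QALY weight
    absence_days: np.ndarray  # (n, T)
    death_in_employment: np.ndarray  # (n, T) bool
    events: dict  # name -> (n, T) bool
    cohort_ids: np.ndarray  # (n,)
    baseline_employed: np.ndarray  # (n,) bool

    @property
    def n(self) -> int:
        return self.cost.shape[0]

    @property
    def n_cycles(self) -> int:
        return self.cost.shape[1]


@dataclass
class IncrementalResult:
    """Intervention-vs-do-nothing comparison for one scenario pair.

    Per-person discounted quantities; `net_benefit = lambda * d_qaly - d_cost`
    holds exactly, overall, per horizon and per quintile.
    """

    d_qaly: float
    d_cost: float
    net_benefit: float
    lambda_wtp: float
    by_horizon: dict  # label -> {d_qaly, d_cost, net_benefit}
    by_imd: pd.DataFrame  # per-quintile sums and per-person means
    d_events: dict  # event -> delta count per PAPER_POPULATION
    employer: dict
    n: int
    mc_se_net_benefit: float


def _horizon_label(h) -> str:
    return "lifetime" if h is None else f"{h}y"


def _per_person(arr: np.ndarray, dfac: np.ndarray, h: int | None) -> np.ndarray:
    T = arr.shape[1]
    stop = T if h is None else min(h, T)
    return arr[:, :stop] @ dfac[:stop]


def aggregate(led_i: Ledger, led_0: Ledger, cohort: pd.DataFrame, cfg: EconConfig) -> IncrementalResult:
    """Aggregate two common-random-number ledgers into an IncrementalResult.

    Quintile splits partition the overall sums exactly; event deltas are
    rescaled per 5,000,000 simulated individuals.
    """
    cfg.validate()
    if led_i.cost.shape != led_0.cost.shape or not np.array_equal(
        led_i.cohort_ids, led_0.cohort_ids
    ):
        raise ValueError("mismatched cohorts: ledgers must come from the same cohort")
    n, T = led_i.cost.shape
    dfac = discount_factors(T, cfg.discount_rate)

    dq_pp = {}
    dc_pp = {}
    for h in cfg.horizons:
        dq_pp[h] = _per_person(led_i.utility, dfac, h) - _per_person(led_0.utility, dfac, h)
        dc_pp[h] = _per_person(led_i.cost, dfac, h) - _per_person(led_0.cost, dfac, h)

    by_horizon = {}
    for h in cfg.horizons:
        dq, dc = dq_pp[h].mean(), dc_pp[h].mean()
        by_horizon[_horizon_label(h)] = {
            "d_qaly": dq,
            "d_cost": dc,
            "net_benefit": float(incremental_net_benefit(dq, dc, cfg.lambda_wtp)),
        }

    life = None if None in cfg.horizons else max(cfg.horizons)
    dq_life, dc_life = dq_pp[life], dc_pp[life]
    nb_pp = incremental_net_benefit(dq_life, dc_life, cfg.lambda_wtp)

    imd = cohort["imd_quintile"].to_numpy()
    rows = []
    for q in (1, 2, 3, 4, 5):
        m = imd == q
        rows.append(
            {
                "imd_quintile": q,
                "n": int(m.sum()),
                "d_qaly_sum": float(dq_life[m].sum()),
                "d_cost_sum": float(dc_life[m].sum()),
                "net_benefit_sum": float(nb_pp[m].sum()),
            }
        )
    by_imd = pd.DataFrame(rows)
    by_imd["d_qaly_per_person"] = by_imd["d_qaly_sum"] / n
    by_imd["d_cost_per_person"] = by_imd["d_cost_sum"] / n

    scale = PAPER_POPULATION / n
    d_events = {
        name: float((led_i.events[name].sum() - led_0.events[name].sum()) * scale)
        for name in led_i.events
    }

    return IncrementalResult(
        d_qaly=float(dq_life.mean()),
        d_cost=float(dc_life.mean()),
        net_benefit=float(incremental_net_benefit(dq_life.mean(), dc_life.mean(), cfg.lambda_wtp)),
        lambda_wtp=cfg.lambda_wtp,
        by_horizon=by_horizon,
        by_imd=by_imd,
        d_events=d_events,
        employer=employer_costs(led_i, led_0, cfg),
        n=n,
        mc_se_net_benefit=float(nb_pp.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
    )


def employer_costs(led_i: Ledger, led_0: Ledger, cfg: EconConfig) -> dict:
    """Incremental employer impact by the friction-cost method.

    Absence days and deaths-in-employment deltas per 5,000,000 simulated
    individuals (discounted), and employer cost per individual in
    employment at baseline.
    """
    n, T = led_i.cost.shape
    n_employed = int(led_i.baseline_employed.sum())
    dfac = discount_factors(T, cfg.discount_rate)
    fr = cfg.friction

    d_days = float(((led_i.absence_days - led_0.absence_days) @ dfac).sum())
    d_deaths = float(
        ((led_i.death_in_employment.astype(float) - led_0.death_in_employment) @ dfac).sum()
    )
    total_cost = fr.daily_wage * d_days + fr.recruitment_cost * d_deaths
    scale = PAPER_POPULATION / n
    return {
        "absence_days_per_5m": d_days * scale,
        "deaths_in_employment_per_5m": d_deaths * scale,
        "cost_per_employed": total_cost / n_employed if n_employed else 0.0,
        "n_employed_baseline": n_employed,
    }
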