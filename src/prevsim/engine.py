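"""Scenario orchestration: yearly-cycle runs and intervention comparisons.

A scenario run simulates every cohort member until death or a maximum age,
in yearly cycles with a fixed, pinned stage order:

    (0) enrolment — and, for the screening policy, the one-off screening
        cascade — at the start of the first cycle only;
    (1) metabolic trajectory update (ageing, drifts, decayed intervention
        delta, one-off treatment effects from last cycle's diagnoses);
    (2) GP visit (diagnosis of diabetes / hypertension / dyslipidaemia);
    (3) annual health events and death;
    (4) economics ledger (costs, QALY weight, absence days).

Cycle 0 is the first simulated year and is undiscounted; "year 1" of an
intervention is cycle 0.  All randomness is drawn from counter-based
streams keyed by (seed, channel, cycle) with person slot as index, so an
intervention run and its do-nothing twin consume identical random numbers
everywhere the intervention does not touch (common random numbers): with
effects and costs zeroed, every incremental delta is exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import care_events, econ, interventions, rng as crn, synthpop, trajectories

__all__ = [
    "ScenarioConfig",
    "STAGE_ORDER",
    "state_from_frame",
    "frame_from_state",
    "run_scenario",
    "scenario_result",
    "compare",
]

STAGE_ORDER = ("trajectories", "gp_visit", "annual_events", "econ_ledger")

log = logging.getLogger(__name__)


@dataclass
class ScenarioConfig:
    """Everything needed to run one scenario (and its do-nothing twin)."""

    population: Union[synthpop.PopulationSpec, str] = field(
        default_factory=synthpop.PopulationSpec
    )
    cohort_size: Optional[int] = None  # overrides the spec's n
    seed: int = 0
    intervention: Union[str, interventions.InterventionDef, None] = None
    trajectory: trajectories.TrajectoryParams = field(
        default_factory=trajectories.TrajectoryParams
    )
    gp: care_events.GPConfig = field(default_factory=care_events.GPConfig)
    screening: care_events.ScreeningConfig = field(
        default_factory=care_events.ScreeningConfig
    )
    equations: care_events.RiskEquationSet = field(
        default_factory=care_events.RiskEquationSet
    )
    econ: econ.EconConfig = field(default_factory=econ.EconConfig)
    max_age: int = 110
    max_cycles: Optional[int] = None
    retirement_age: int = 65

    def validate(self) -> None:
        if self.cohort_size is not None and self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")
        if isinstance(self.population, synthpop.PopulationSpec):
            spec = self.population
            if self.cohort_size is not None:
                spec = _replace_spec(spec, n=self.cohort_size, seed=self.seed)
            spec.validate()
        if isinstance(self.intervention, str):
            if self.intervention not in interventions.builtin_names():
                raise ValueError(
                    f"unknown intervention '{self.intervention}'; "
                    f"built-ins are {list(interventions.builtin_names())}"
                )
        self.trajectory.validate()
        self.screening.validate()
        self.econ.validate()

    def resolve_intervention(self) -> Optional[interventions.InterventionDef]:
        if self.intervention is None:
            return None
        if isinstance(self.intervention, interventions.InterventionDef):
            return self.intervention
        return interventions.builtin_interventions()[self.intervention]


def _replace_spec(spec, **kw):
    import dataclasses

    return dataclasses.replace(spec, **kw)


_STR_COLS = ("sex", "ethnicity", "smoker")


def state_from_frame(df: pd.DataFrame) -> dict:
    """Columnar simulation state from a cohort DataFrame."""
    state = {}
    for c in synthpop.COLUMNS:
        if c == "diabetes_onset_year":
            state[c] = df[c].to_numpy(dtype="float64", na_value=np.nan).copy()
        elif c in _STR_COLS:
            state[c] = df[c].to_numpy(dtype=object).copy()
        elif c in ("id", "age", "imd_quintile"):
            state[c] = df[c].to_numpy(dtype=np.int64).copy()
        elif df[c].dtype == bool:
            state[c] = df[c].to_numpy(dtype=bool).copy()
        else:
            state[c] = df[c].to_numpy(dtype=float).copy()
    state["baseline_age"] = state["age"].copy()
    return state


def frame_from_state(state: dict) -> pd.DataFrame:
    df = pd.DataFrame({c: state[c] for c in synthpop.COLUMNS if c != "diabetes_onset_year"})
    onset = state["diabetes_onset_year"]
    df["diabetes_onset_year"] = pd.array(
        [pd.NA if np.isnan(v) else int(v) for v in onset], dtype="Int64"
    )
    return df[list(synthpop.COLUMNS)]


def _resolve_cohort(cfg: ScenarioConfig) -> pd.DataFrame:
    if isinstance(cfg.population, str):
        df = synthpop.read_population(cfg.population)
        if cfg.cohort_size is not None:
            df = df.iloc[: cfg.cohort_size].reset_index(drop=True)
        return df
    spec = cfg.population
    kw = {"seed": cfg.seed}
    if cfg.cohort_size is not None:
        kw["n"] = cfg.cohort_size
    spec = _replace_spec(spec, **kw)
    return synthpop.generate_population(spec)


def _masked_advance(state, params, idelta, tdelta, active):
    """Advance only the active (alive, under max age) subset."""
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return
    sub = {k: (v[idx] if isinstance(v, np.ndarray) else v) for k, v in state.items()
           if k != "slopes"}
    sub["slopes"] = {f: s[idx] for f, s in state["slopes"].items()}
    sub_id = {f: np.asarray(d)[idx] if np.ndim(d) else d for f, d in idelta.items()}
    sub_td = {f: np.asarray(d)[idx] if np.ndim(d) else d for f, d in tdelta.items()}
    trajectories.advance_metabolic(sub, params, sub_id, sub_td)
    for f in trajectories.FACTORS:
        state[f][idx] = sub[f]
    state["age"][idx] = sub["age"]


_FROM_CONFIG = object()  # sentinel: take the intervention from the config


def run_scenario(
    cfg: ScenarioConfig,
    cohort: pd.DataFrame | None = None,
    idef=_FROM_CONFIG,
) -> econ.Ledger:
    """Simulate one scenario; deterministic given cfg.seed.

    `cohort` and `idef` override the config (used by compare/PSA so both
    scenario arms share one cohort).  Pass idef=None to force do-nothing
    regardless of the config's intervention.
    """
    cfg.validate()
    if cohort is None:
        cohort = _resolve_cohort(cfg)
    if idef is _FROM_CONFIG:
        idef = cfg.resolve_intervention()
    state = state_from_frame(cohort)
    n = state["age"].shape[0]
    seed = cfg.seed

    state["slopes"] = trajectories.draw_slopes(
        n, cfg.trajectory, crn.generator(seed, "slopes")
    )
    state["employed_now"] = (
        state["employed"] & (state["age"] < cfg.retirement_age) & state["alive"]
    )
    # biological onset for anyone already over the diagnostic threshold
    over = state["hba1c"] >= cfg.gp.diabetes_threshold
    state["diabetes_onset_year"] = np.where(
        over & np.isnan(state["diabetes_onset_year"]), 0.0, state["diabetes_onset_year"]
    )

    T = cfg.max_cycles
    if T is None:
        T = int(cfg.max_age - state["age"].min())

    # --- stage 0: enrolment / screening cascade (first cycle only) -----
    enr = None
    screen_cost0 = np.zeros(n)
    if idef is not None:
        if idef.screening:
            cascade = care_events.screening_cascade(state, cfg.screening, seed, cycle=0)
            screen_cost0 = cascade["nhs_cost"]
            enr = interventions.enrol(
                state, idef, seed, participants_override=cascade["accepted"]
            )
        else:
            enr = interventions.enrol(state, idef, seed)

    led = econ.Ledger(
        cost=np.zeros((n, T)),
        utility=np.zeros((n, T)),
        absence_days=np.zeros((n, T)),
        death_in_employment=np.zeros((n, T), dtype=bool),
        events={
            name: np.zeros((n, T), dtype=bool)
            for name in care_events.EVENT_ORDER + care_events.DEATH_ORDER
        },
        cohort_ids=state["id"].copy(),
        baseline_employed=state["employed"].copy(),
    )

    prev_level = {f: np.zeros(n) for f in trajectories.FACTORS}
    new_dx = {"diabetes": np.zeros(n, bool), "hypertension": np.zeros(n, bool),
              "dyslipidaemia": np.zeros(n, bool)}

    log.info("simulating %d individuals for up to %d cycles", n, T)
    person_years = 0
    next_mark = 10_000

    for t in range(T):
        active = state["alive"] & (state["age"] < cfg.max_age)
        if not active.any():
            break
        person_years += int(active.sum())
        if person_years >= next_mark:
            log.info("cycle %d/%d: %d person-years simulated, %d alive",
                     t + 1, T, person_years, int(active.sum()))
            next_mark = person_years + max(10_000, n)

        # (1) trajectories
        idelta = {}
        if enr is not None:
            year = t + 1  # intervention year, 1-based
            level = interventions.active_effect(enr.effects, year, idef.decay_duration)
            idelta = {f: level[f] - prev_level[f] for f in level}
            prev_level = level
        te = cfg.trajectory.treatment_effects
        tdelta = {
            "hba1c": te.get("hba1c", 0.0) * new_dx["diabetes"],
            "sbp": te.get("sbp", 0.0) * new_dx["hypertension"],
            "total_chol": te.get("total_chol", 0.0) * new_dx["dyslipidaemia"],
        }
        _masked_advance(state, cfg.trajectory, idelta, tdelta, active)

        # people ageing past the cap are censored (no death event recorded)
        state["alive"] &= state["age"] <= cfg.max_age
        over = state["hba1c"] >= cfg.gp.diabetes_threshold
        state["diabetes_onset_year"] = np.where(
            over & np.isnan(state["diabetes_onset_year"]) & state["alive"],
            float(t),
            state["diabetes_onset_year"],
        )

        # (2) GP visit
        new_dx = care_events.gp_visit(state, cfg.gp, t, seed)

        # (3) annual events
        employed_before = state["employed_now"] & state["alive"]
        events = care_events.annual_events(state, cfg.equations, t, seed)
        died = events["death_cvd"] | events["death_cancer"] | events["death_other"]
        for name, fired in events.items():
            led.events[name][:, t] = fired
        led.death_in_employment[:, t] = died & employed_before

        # (4) economics
        state["employed_now"] = (
            state["employed"] & (state["age"] < cfg.retirement_age) & state["alive"]
        )
        # intervention/screening costs are incurred at delivery, so they are
        # charged to everyone alive at the start of the cycle even if they
        # die within it (unlike routine care, which death-in-cycle voids)
        extra = np.zeros(n)
        if enr is not None:
            extra = extra + enr.cost_nhs_by_year.get(t + 1, 0.0)
            if t == 0:
                extra = extra + screen_cost0
        led.cost[:, t] = econ.annual_cost(
            state, cfg.econ.cost_table, events, cfg.econ.treatment_costs
        ) + np.where(active, extra, 0.0)
        led.utility[:, t] = econ.annual_utility(state, cfg.econ)
        led.absence_days[:, t] = econ.annual_absence(state, cfg.econ, t)

    return led


def scenario_result(led: econ.Ledger, cfg: ScenarioConfig) -> dict:
    """Absolute discounted per-person summary of a single scenario run."""
    e = cfg.econ
    dfac = econ.discount_factors(led.n_cycles, e.discount_rate)
    out = {"n": led.n, "n_cycles": led.n_cycles, "horizons": {}}
    for h in e.horizons:
        stop = led.n_cycles if h is None else min(h, led.n_cycles)
        label = "lifetime" if h is None else f"{h}y"
        out["horizons"][label] = {
            "mean_cost": float((led.cost[:, :stop] @ dfac[:stop]).mean()),
            "mean_qaly": float((led.utility[:, :stop] @ dfac[:stop]).mean()),
        }
    out["events_per_5m"] = {
        name: float(arr.sum() * econ.PAPER_POPULATION / led.n)
        for name, arr in led.events.items()
    }
    return out


def compare(
    cfg: ScenarioConfig,
    intervention: Union[str, interventions.InterventionDef, None] = None,
) -> econ.IncrementalResult:
    """Run do-nothing and the intervention with common random numbers and
    aggregate the incremental result.  Non-participants contribute exactly
    zero to every delta."""
    cfg.validate()
    idef = intervention
    if idef is None:
        idef = cfg.resolve_intervention()
    elif isinstance(idef, str):
        if idef not in interventions.builtin_names():
            raise ValueError(
                f"unknown intervention '{idef}'; built-ins are "
                f"{list(interventions.builtin_names())}"
            )
        idef = interventions.builtin_interventions()[idef]
    if idef is None:
        raise ValueError("compare requires an intervention")

    cohort = _resolve_cohort(cfg)
    led_0 = run_scenario(cfg, cohort=cohort.copy(deep=True), idef=None)
    led_i = run_scenario(cfg, cohort=cohort.copy(deep=True), idef=idef)
    return econ.aggregate(led_i, led_0, cohort, cfg.econ)
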