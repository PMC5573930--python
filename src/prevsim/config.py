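"""Scenario configuration loading (YAML/JSON) and run metadata."""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml

from . import care_events, econ, engine, synthpop, trajectories


def _apply(obj, mapping: dict, path=""):
    """Recursively apply a nested mapping of overrides onto a config tree."""
    for key, val in mapping.items():
        here = f"{path}{key}"
        if not hasattr(obj, key):
            raise KeyError(f"unknown config key '{here}'")
        cur = getattr(obj, key)
        if dataclasses.is_dataclass(cur) and isinstance(val, dict):
            _apply(cur, val, f"{here}.")
        elif isinstance(cur, dict) and isinstance(val, dict):
            cur.update(val)
        else:
            setattr(obj, key, val)


def scenario_config_from_dict(d: dict) -> engine.ScenarioConfig:
    """Build a ScenarioConfig from a plain mapping (parsed YAML/JSON).

    Recognised top-level blocks: population (PopulationSpec fields or a
    `file` path), intervention (built-in name or a YAML path under `file`),
    trajectory, gp, screening, econ (with nested friction), equations
    (`file` pointing at a coefficient JSON), plus scalars seed,
    cohort_size, max_cycles, max_age, retirement_age.
    """
    d = dict(d or {})
    cfg = engine.ScenarioConfig()

    pop = d.pop("population", None)
    if isinstance(pop, str):
        cfg.population = pop
    elif isinstance(pop, dict):
        if "file" in pop:
            cfg.population = pop["file"]
        else:
            spec = synthpop.PopulationSpec()
            _apply(spec, pop, "population.")
            cfg.population = spec

    intv = d.pop("intervention", None)
    if isinstance(intv, dict) and "file" in intv:
        from . import interventions as _iv

        cfg.intervention = _iv.load_intervention(intv["file"])
    elif intv is not None:
        cfg.intervention = intv

    eqs = d.pop("equations", None)
    if isinstance(eqs, dict) and "file" in eqs:
        cfg.equations = care_events.RiskEquationSet.from_json(eqs["file"])
    elif isinstance(eqs, dict):
        _apply(cfg.equations, eqs, "equations.")

    ec = d.pop("econ", None)
    if isinstance(ec, dict):
        ec = dict(ec)
        table = ec.pop("cost_table", None)
        if isinstance(table, str):
            cfg.econ.cost_table = econ.load_cost_table(table)
        _apply(cfg.econ, ec, "econ.")

    for block, target in (
        ("trajectory", cfg.trajectory),
        ("gp", cfg.gp),
        ("screening", cfg.screening),
    ):
        b = d.pop(block, None)
        if isinstance(b, dict):
            _apply(target, b, f"{block}.")

    _apply(cfg, d)
    cfg.validate()
    return cfg


def load_scenario_config(path) -> engine.ScenarioConfig:
    with open(path) as fh:
        return scenario_config_from_dict(yaml.safe_load(fh) or {})


def config_hash(cfg: engine.ScenarioConfig) -> str:
    """Stable hash of the (serializable part of the) configuration."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        try:
            return o.tolist()
        except AttributeError:
            return repr(o)

    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
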