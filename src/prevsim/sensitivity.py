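"""One-way and probabilistic sensitivity analysis (CEAC / CEAF).

One-way analysis re-runs the intervention comparison over a grid of values
for a single parameter addressed by dotted path into the scenario config
(e.g. ``econ.lambda_wtp`` or ``screening.programme_uptake``), everything
else — including the random streams — held fixed.

The probabilistic analysis repeats the comparison over parameter sets
sampled from uncertainty distributions: intervention effects are Normal
with SD = (upper - lower)/(2 x 1.96) from their 95% intervals, truncated
to the interval so a beneficial effect cannot flip sign beyond the far
bound; uptake probabilities may optionally be sampled Beta.  Each run uses
a fresh cohort seeded from the master seed, and records per-person
incremental cost and QALYs per strategy.  The cost-effectiveness
acceptability curve (CEAC) gives, per willingness-to-pay, the fraction of
runs in which each strategy (including do-nothing) has the greatest net
benefit, ties split equally; the frontier (CEAF) reports the strategy
maximizing *mean* net benefit together with its CEAC value.
"""

from __future__ import annotations

import copy
import dataclasses
import difflib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import engine, interventions

__all__ = [
    "PSASpec",
    "one_way",
    "set_by_path",
    "sample_intervention",
    "psa",
    "ceac",
    "ceaf",
    "DO_NOTHING",
]

DO_NOTHING = "do_nothing"


def _leaves(obj, prefix=""):
    """Dotted paths of all settable leaves of a config tree (for suggestions)."""
    out = []
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        for f in dataclasses.fields(obj):
            out.extend(_leaves(getattr(obj, f.name), f"{prefix}{f.name}."))
    elif isinstance(obj, dict):
        for k in obj:
            out.extend(_leaves(obj[k], f"{prefix}{k}."))
    else:
        out.append(prefix[:-1])
    return out


def set_by_path(cfg, path: str, value) -> None:
    """Set a config parameter by dotted path, in place.

    Unknown paths raise KeyError with a nearest-match suggestion.
    """
    parts = path.split(".")
    obj = cfg
    for i, part in enumerate(parts):
        last = i == len(parts) - 1
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            if not hasattr(obj, part):
                _suggest(cfg, path)
            if last:
                setattr(obj, part, value)
            else:
                obj = getattr(obj, part)
        elif isinstance(obj, dict):
            if part not in obj:
                _suggest(cfg, path)
            if last:
                obj[part] = value
            else:
                obj = obj[part]
        else:
            _suggest(cfg, path)


def _suggest(cfg, path):
    close = difflib.get_close_matches(path, _leaves(cfg), n=1)
    hint = f"; did you mean '{close[0]}'?" if close else ""
    raise KeyError(f"unknown parameter path '{path}'{hint}")


def one_way(
    cfg: engine.ScenarioConfig,
    param_path: str,
    values,
    intervention=None,
) -> pd.DataFrame:
    """Net-benefit table over a grid of values of one parameter."""
    rows = []
    for v in values:
        cfg_v = copy.deepcopy(cfg)
        set_by_path(cfg_v, param_path, v)
        res = engine.compare(cfg_v, intervention)
        row = {"param": param_path, "value": v,
               "d_qaly": res.d_qaly, "d_cost": res.d_cost,
               "net_benefit": res.net_benefit}
        for label, h in res.by_horizon.items():
            row[f"net_benefit_{label}"] = h["net_benefit"]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PSASpec:
    n_runs: int = 2000
    individuals_per_run: int = 20_000
    lambda_grid: tuple = tuple(range(0, 50_001, 2_500))
    seed: int = 0
    sample_uptake: bool = False  # also draw uptakes ~ Beta around their points
    uptake_kappa: float = 100.0  # Beta concentration when sampling uptakes

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.individuals_per_run < 1:
            raise ValueError("individuals_per_run must be >= 1")


def _sample_effect(e: interventions.Effect, rng) -> interventions.Effect:
    def draw(point, low, high):
        if low is None or high is None:
            return point
        sd = (high - low) / (2 * 1.959963984540054)
        if sd <= 0:
            return point
        lo, hi = min(low, high), max(low, high)
        a, b = (lo - point) / sd, (hi - point) / sd
        return float(stats.truncnorm.rvs(a, b, loc=point, scale=sd, random_state=rng))

    if e.age_bands is not None:
        bands = [[lo, hi, draw(p, l, h), l, h] for lo, hi, p, l, h in e.age_bands]
        return dataclasses.replace(e, age_bands=bands, allow_unbracketed=True)
    return dataclasses.replace(
        e, point=draw(e.point, e.low, e.high), allow_unbracketed=True
    )


def sample_intervention(
    idef: interventions.InterventionDef, rng, sample_uptake=False, uptake_kappa=100.0
) -> interventions.InterventionDef:
    """One PSA draw of an intervention's uncertain parameters.

    Degenerate intervals (no interval, or zero width) return the point
    estimate, so a fully degenerate spec collapses to the deterministic
    definition.
    """
    arms = []
    for arm in idef.arms:
        bundles = [
            dataclasses.replace(
                b, effects={f: _sample_effect(e, rng) for f, e in b.effects.items()}
            )
            for b in arm.bundles
        ]
        uptake = arm.uptake
        if sample_uptake and 0.0 < uptake < 1.0:
            a = uptake * uptake_kappa
            bb = (1 - uptake) * uptake_kappa
            uptake = float(rng.beta(a, bb))
        arms.append(dataclasses.replace(arm, bundles=bundles, uptake=uptake))
    return dataclasses.replace(idef, arms=arms)


def run_seeds(master_seed: int, n_runs: int) -> np.ndarray:
    """Per-run simulation seeds, deterministic given the master seed."""
    ss = np.random.SeedSequence(master_seed)
    return ss.generate_state(n_runs, dtype=np.uint32).astype(np.int64)


def psa(
    spec: PSASpec,
    cfg: engine.ScenarioConfig,
    idefs: dict | list | None = None,
) -> pd.DataFrame:
    """PSA draws: one row per (run, strategy) with per-person incremental
    lifetime cost and QALYs vs do-nothing on that run's cohort."""
    spec.validate()
    if idefs is None:
        idefs = interventions.builtin_interventions()
    if isinstance(idefs, list):
        idefs = {d.name: d for d in idefs}
    seeds = run_seeds(spec.seed, spec.n_runs)
    rows = []
    for r in range(spec.n_runs):
        cfg_r = copy.deepcopy(cfg)
        cfg_r.seed = int(seeds[r])
        cfg_r.cohort_size = spec.individuals_per_run
        param_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, r, 77]))
        for name, idef in idefs.items():
            idef_s = sample_intervention(
                idef, param_rng, spec.sample_uptake, spec.uptake_kappa
            )
            res = engine.compare(cfg_r, idef_s)
            rows.append(
                {"run": r, "strategy": name, "d_cost": res.d_cost, "d_qaly": res.d_qaly}
            )
    return pd.DataFrame(rows)


def ceac(draws: pd.DataFrame, lambda_grid) -> pd.DataFrame:
    """Probability each strategy (incl. do-nothing) is cost-effective vs
    willingness-to-pay; ties split equally; curves sum to 1 at each lambda."""
    if draws.empty:
        raise ValueError("ceac requires at least one PSA draw")
    strategies = sorted(draws["strategy"].unique()) + [DO_NOTHING]
    runs = sorted(draws["run"].unique())
    nb = pd.DataFrame(0.0, index=runs, columns=strategies)
    rows = []
    for lam in lambda_grid:
        for s in strategies:
            nb[s] = 0.0
        for s, grp in draws.groupby("strategy"):
            nb.loc[grp["run"].to_numpy(), s] = (
                lam * grp["d_qaly"].to_numpy() - grp["d_cost"].to_numpy()
            )
        best = nb.max(axis=1)
        wins = nb.eq(best, axis=0)
        share = wins.div(wins.sum(axis=1), axis=0)
        probs = share.mean(axis=0)
        for s in strategies:
            rows.append({"lambda": lam, "strategy": s, "probability": float(probs[s])})
    return pd.DataFrame(rows)


def ceaf(draws: pd.DataFrame, lambda_grid) -> pd.DataFrame:
    """Frontier: per lambda, the strategy with greatest mean net benefit and
    its CEAC probability (ties broken by strategy name)."""
    curves = ceac(draws, lambda_grid)
    strategies = sorted(draws["strategy"].unique()) + [DO_NOTHING]
    mean_dq = draws.groupby("strategy")["d_qaly"].mean().reindex(strategies).fillna(0.0)
    mean_dc = draws.groupby("strategy")["d_cost"].mean().reindex(strategies).fillna(0.0)
    rows = []
    for lam in lambda_grid:
        mean_nb = lam * mean_dq - mean_dc
        best = mean_nb.sort_index().idxmax()
        p = curves[(curves["lambda"] == lam) & (curves["strategy"] == best)][
            "probability"
        ].iloc[0]
        rows.append(
            {"lambda": lam, "strategy": best, "mean_net_benefit": float(mean_nb[best]),
             "probability": float(p)}
        )
    return pd.DataFrame(rows)
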