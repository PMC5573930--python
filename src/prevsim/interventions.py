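"""The five built-in prevention policies as data, plus enrolment and decay.

A policy (InterventionDef) is one or more *arms*, each with a targeting
rule over individual characteristics, an optional random coverage fraction
(e.g. 20% of workplaces take part), an uptake probability, and one or more
effect *bundles* — independent sub-lotteries such as the workplace fruit
and milk switches, each carrying 1-year changes in BMI, HbA1c, SBP and/or
total cholesterol with their uncertainty intervals.  Costs are per covered
(targeted) person or per participant, on a year schedule, charged to the
configured payer (only NHS costs enter the cost-effectiveness ledger).

Effectiveness is full in year 1 and decays linearly to zero at the decay
duration (default 5 years): weight(t) = max(0, (D - t)/(D - 1)).  Effects
are level shifts relative to the counterfactual trajectory — they do not
compound year on year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources as importlib_resources

import numpy as np
import yaml

from . import rng as crn

__all__ = [
    "Effect",
    "Bundle",
    "Arm",
    "InterventionDef",
    "EnrolmentResult",
    "InterventionError",
    "builtin_interventions",
    "builtin_names",
    "load_intervention",
    "decay_weight",
    "active_effect",
    "enrol",
    "FACTORS",
]

FACTORS = ("bmi", "hba1c", "sbp", "total_chol")

BUILTIN_NAMES = ("soft_drinks_tax", "retail", "workplace", "community", "high_risk")


class InterventionError(ValueError):
    pass


@dataclass
class Effect:
    """A 1-year change in one risk factor, with its 95% interval.

    Either a flat (point, low, high) or an age-banded table
    [(lo_age, hi_age, point, low, high), ...].  Negative points are
    beneficial (the factor is reduced).
    """

    point: float | None = None
    low: float | None = None
    high: float | None = None
    age_bands: list | None = None
    allow_unbracketed: bool = False

    def validate(self, name: str = "effect") -> None:
        rows = self.age_bands or [(None, None, self.point, self.low, self.high)]
        for row in rows:
            _, _, p, lo, hi = row
            if p is None:
                raise InterventionError(f"{name}: point estimate missing")
            if lo is not None and hi is not None and not self.allow_unbracketed:
                if not (lo <= p <= hi):
                    raise InterventionError(
                        f"{name}: interval ({lo}, {hi}) does not bracket point {p}"
                    )

    def point_for_age(self, age) -> np.ndarray:
        """Point effect per person, resolved by (baseline) age band."""
        age = np.asarray(age)
        if self.age_bands is None:
            return np.full(age.shape, float(self.point))
        out = np.zeros(age.shape, dtype=float)
        for lo, hi, p, *_ in self.age_bands:
            out[(age >= lo) & (age <= hi)] = p
        return out

    def sd(self) -> float:
        """Normal SD implied by the 95% interval, (high - low)/(2*1.96)."""
        if self.low is None or self.high is None:
            return 0.0
        return (self.high - self.low) / (2 * 1.959963984540054)


@dataclass
class Bundle:
    name: str
    probability: float = 1.0
    effects: dict = field(default_factory=dict)  # factor -> Effect


@dataclass
class Arm:
    name: str
    target: dict = field(default_factory=dict)
    coverage: float = 1.0
    uptake: float = 1.0
    bundles: list = field(default_factory=list)
    cost_per_target: dict = field(default_factory=dict)  # year (1-based) -> GBP
    cost_per_participant: dict = field(default_factory=dict)


@dataclass
class InterventionDef:
    name: str
    description: str = ""
    payer: str = "nhs"  # nhs | private | none
    decay_duration: int = 5
    screening: bool = False  # participants come from the screening cascade
    arms: list = field(default_factory=list)

    def validate(self) -> None:
        if self.payer not in ("nhs", "private", "none"):
            raise InterventionError(f"{self.name}: payer must be nhs/private/none")
        if self.decay_duration < 2:
            raise InterventionError(f"{self.name}: decay_duration must be >= 2")
        for arm in self.arms:
            for p, label in ((arm.uptake, "uptake"), (arm.coverage, "coverage")):
                if not 0.0 <= p <= 1.0:
                    raise InterventionError(f"{self.name}/{arm.name}: {label} not in [0, 1]")
            for b in arm.bundles:
                if not 0.0 <= b.probability <= 1.0:
                    raise InterventionError(
                        f"{self.name}/{arm.name}/{b.name}: probability not in [0, 1]"
                    )
                for f, e in b.effects.items():
                    e.validate(f"{self.name}/{arm.name}/{b.name}/{f}")

    def zeroed(self) -> "InterventionDef":
        """A copy with every effect point and cost set to zero (CRN null)."""
        arms = []
        for arm in self.arms:
            bundles = [
                Bundle(
                    b.name,
                    b.probability,
                    {
                        f: replace(e, point=0.0 if e.point is not None else None,
                                   age_bands=None if e.age_bands is None else
                                   [[lo, hi, 0.0, lo2, hi2] for lo, hi, _, lo2, hi2 in e.age_bands],
                                   allow_unbracketed=True)
                        for f, e in b.effects.items()
                    },
                )
                for b in arm.bundles
            ]
            arms.append(replace(arm, bundles=bundles, cost_per_target={}, cost_per_participant={}))
        return replace(self, arms=arms)


def _effect_from_dict(d) -> Effect:
    if isinstance(d, dict) and "age_bands" in d:
        return Effect(age_bands=[list(r) for r in d["age_bands"]],
                      allow_unbracketed=d.get("allow_unbracketed", False))
    return Effect(
        point=d.get("point"),
        low=d.get("low"),
        high=d.get("high"),
        allow_unbracketed=d.get("allow_unbracketed", False),
    )


def _def_from_dict(d: dict) -> InterventionDef:
    arms = []
    for a in d.get("arms", []):
        bundles = [
            Bundle(
                name=b["name"],
                probability=float(b.get("probability", 1.0)),
                effects={f: _effect_from_dict(e) for f, e in b.get("effects", {}).items()},
            )
            for b in a.get("bundles", [])
        ]
        arms.append(
            Arm(
                name=a["name"],
                target=a.get("target", {}),
                coverage=float(a.get("coverage", 1.0)),
                uptake=float(a.get("uptake", 1.0)),
                bundles=bundles,
                cost_per_target={int(k): float(v) for k, v in a.get("cost_per_target", {}).items()},
                cost_per_participant={
                    int(k): float(v) for k, v in a.get("cost_per_participant", {}).items()
                },
            )
        )
    idef = InterventionDef(
        name=d["name"],
        description=d.get("description", ""),
        payer=d.get("payer", "nhs"),
        decay_duration=int(d.get("decay_duration", 5)),
        screening=bool(d.get("screening", False)),
        arms=arms,
    )
    idef.validate()
    return idef


def load_intervention(path) -> InterventionDef:
    """Load an InterventionDef from a user YAML file."""
    with open(path) as fh:
        return _def_from_dict(yaml.safe_load(fh))


def builtin_names() -> tuple:
    return BUILTIN_NAMES


def builtin_interventions() -> dict:
    """The five shipped policies, keyed by name."""
    out = {}
    for name in BUILTIN_NAMES:
        res = importlib_resources.files("prevsim.resources.interventions").joinpath(
            f"{name}.yaml"
        )
        with res.open() as fh:
            out[name] = _def_from_dict(yaml.safe_load(fh))
    return out


def decay_weight(years_since_start, duration: int):
    """Linear effect decay: 1 in year 1, 0 at year `duration` and beyond."""
    if duration < 2:
        raise InterventionError("decay duration must be >= 2 years")
    t = np.asarray(years_since_start, dtype=float)
    if np.any(t < 1):
        raise InterventionError("years_since_start must be >= 1")
    w = np.maximum(0.0, (duration - t) / (duration - 1.0))
    return w if w.ndim else float(w)


def target_mask(state: dict, target: dict) -> np.ndarray:
    """Evaluate an arm's targeting rule over the cohort."""
    n = state["age"].shape[0]
    mask = np.ones(n, dtype=bool)
    for key, val in target.items():
        if key == "all":
            continue
        elif key == "bmi_gt":
            mask &= state["bmi"] > val
        elif key == "bmi_lt":
            mask &= state["bmi"] < val
        elif key in state:
            mask &= state[key] == val
        else:
            raise InterventionError(f"unknown target field '{key}'")
    return mask


@dataclass
class EnrolmentResult:
    """Who participates and what they get.

    effects: per-factor point-effect arrays (n,) — zero for non-participants;
    cost_nhs_by_year: {1-based year: per-person GBP array} for NHS-payer costs.
    """

    participants: np.ndarray
    targeted: np.ndarray
    effects: dict
    cost_nhs_by_year: dict


def enrol(
    state: dict,
    idef: InterventionDef,
    seed: int,
    participants_override: np.ndarray | None = None,
) -> EnrolmentResult:
    """Resolve targeting, coverage, uptake and bundle lotteries.

    Deterministic given the seed (counter-based streams keyed per arm and
    bundle).  For screening-based policies the participant set is supplied
    by the screening cascade via `participants_override`.
    """
    idef.validate()
    n = state["age"].shape[0]
    effects = {f: np.zeros(n) for f in FACTORS}
    cost: dict[int, np.ndarray] = {}
    all_participants = np.zeros(n, dtype=bool)
    all_targeted = np.zeros(n, dtype=bool)

    def add_cost(year, mask, amount):
        if amount == 0.0 or not mask.any():
            return
        cost.setdefault(year, np.zeros(n))
        cost[year] = cost[year] + np.where(mask, amount, 0.0)

    for ai, arm in enumerate(idef.arms):
        targeted = state["alive"] & target_mask(state, arm.target)
        if arm.coverage < 1.0:
            targeted &= crn.uniforms(seed, "coverage", ai, n) < arm.coverage
        if participants_override is not None:
            participants = targeted & participants_override
        elif arm.uptake < 1.0:
            participants = targeted & (crn.uniforms(seed, "enrol", ai, n) < arm.uptake)
        else:
            participants = targeted
        all_targeted |= targeted
        all_participants |= participants

        for bi, bundle in enumerate(arm.bundles):
            members = participants
            if bundle.probability < 1.0:
                chan = f"bundle_{min(bi, 1)}"
                members = participants & (
                    crn.uniforms(seed, chan, ai, n) < bundle.probability
                )
            for f, eff in bundle.effects.items():
                effects[f] = effects[f] + np.where(members, eff.point_for_age(state["age"]), 0.0)

        if idef.payer == "nhs":
            for year, amount in arm.cost_per_target.items():
                add_cost(year, targeted, amount)
            for year, amount in arm.cost_per_participant.items():
                add_cost(year, participants, amount)

    return EnrolmentResult(
        participants=all_participants,
        targeted=all_targeted,
        effects=effects,
        cost_nhs_by_year=cost,
    )


def active_effect(effects: dict, years_since_start: int, duration: int) -> dict:
    """Decayed level delta per factor: point effect x decay weight.

    `effects` maps factor -> per-person point effect (or scalar); returns
    the same mapping scaled by decay_weight(years_since_start, duration),
    all-zero beyond the decay duration.
    """
    if years_since_start < 1:
        raise InterventionError("years_since_start must be >= 1")
    w = decay_weight(years_since_start, duration)
    return {f: np.asarray(v, dtype=float) * w for f, v in effects.items()}
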