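"""Synthetic baseline populations for the diabetes-prevention simulator.

The simulator needs a cross-section of English adults (16+) without a
diabetes diagnosis, carrying the joint distribution of demographics,
deprivation, employment and the four metabolic risk factors (BMI, HbA1c,
systolic blood pressure, total cholesterol) that drive disease risk.  The
generator here is a parametric stand-in for resampling a health survey:
categorical marginals for demographics, a Gaussian copula (multivariate
normal on the latent scale) for the metabolic block with configurable
means, SDs and correlations, an additive deprivation gradient on metabolic
means, and a small configurable fraction of undiagnosed diabetes (HbA1c
already over the diagnostic threshold but no diagnosis) — the group a
screening programme exists to find.

HbA1c is stored throughout in DCCT percent; converters to/from IFCC
mmol/mol are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "PopulationSpec",
    "PopulationSpecError",
    "SchemaError",
    "PopulationValidationError",
    "CONDITIONS",
    "COLUMNS",
    "METABOLIC_FACTORS",
    "generate_population",
    "write_population",
    "read_population",
    "hba1c_percent_to_mmol",
    "hba1c_mmol_to_percent",
]

CONDITIONS = (
    "cvd",
    "chf",
    "foot_ulcer",
    "amputation",
    "blindness",
    "renal_failure",
    "osteoarthritis",
    "depression",
    "breast_cancer",
    "colon_cancer",
)

METABOLIC_FACTORS = ("bmi", "hba1c", "sbp", "total_chol")

COLUMNS = (
    "id",
    "age",
    "sex",
    "ethnicity",
    "imd_quintile",
    "employed",
    "bmi",
    "hba1c",
    "sbp",
    "total_chol",
    "hdl_chol",
    "smoker",
    "family_history_diabetes",
    "eq5d_baseline",
    "diagnosed_diabetes",
    "diagnosed_hypertension",
    "diagnosed_dyslipidaemia",
    "diabetes_onset_year",
) + tuple(f"has_{c}" for c in CONDITIONS) + ("alive",)

SEXES = ("male", "female")
ETHNICITIES = ("white", "south_asian", "black", "other")
SMOKER_STATES = ("non", "ex", "current")

EQ5D_FLOOR = -0.594  # EQ-5D-3L minimum (worse than death)


def hba1c_percent_to_mmol(pct):
    """DCCT % -> IFCC mmol/mol."""
    return (np.asarray(pct, dtype=float) - 2.15) * 10.929


def hba1c_mmol_to_percent(mmol):
    """IFCC mmol/mol -> DCCT %."""
    return np.asarray(mmol, dtype=float) / 10.929 + 2.15


class PopulationSpecError(ValueError):
    """A PopulationSpec field is invalid; the message names the field."""


class SchemaError(ValueError):
    """A population file's columns do not match the documented schema."""


class PopulationValidationError(ValueError):
    """A population row violates an Individual invariant."""


@dataclass
class Individual:
    """One simulated person at baseline (convenience single-row view)."""

    id: int
    age: int
    sex: str
    ethnicity: str = "white"
    imd_quintile: int = 3
    employed: bool = False
    bmi: float = 27.0
    hba1c: float = 5.4
    sbp: float = 125.0
    total_chol: float = 5.2
    hdl_chol: float = 1.4
    smoker: str = "non"
    family_history_diabetes: bool = False
    eq5d_baseline: float = 0.9
    diagnosed_diabetes: bool = False
    diagnosed_hypertension: bool = False
    diagnosed_dyslipidaemia: bool = False
    diabetes_onset_year: Optional[int] = None
    condition_flags: frozenset = frozenset()
    alive: bool = True

    def to_row(self) -> dict:
        row = {c: getattr(self, c) for c in COLUMNS if not c.startswith("has_")}
        row["diabetes_onset_year"] = (
            pd.NA if self.diabetes_onset_year is None else self.diabetes_onset_year
        )
        for c in CONDITIONS:
            row[f"has_{c}"] = c in self.condition_flags
        return row


def _default_corr():
    # bmi, hba1c, sbp, total_chol
    return [
        [1.00, 0.25, 0.25, 0.15],
        [0.25, 1.00, 0.10, 0.10],
        [0.25, 0.10, 1.00, 0.15],
        [0.15, 0.10, 0.15, 1.00],
    ]


@dataclass
class PopulationSpec:
    """Parameters of the synthetic baseline population.

    Proportions within each categorical block must sum to 1; the metabolic
    correlation matrix must be positive semi-definite.  Defaults emulate
    the English adult population the simulator targets.
    """

    n: int = 10_000
    seed: int = 0
    # age pyramid: (lo, hi, share), inclusive integer ages
    age_bands: tuple = (
        (16, 29, 0.22),
        (30, 44, 0.25),
        (45, 59, 0.24),
        (60, 74, 0.19),
        (75, 90, 0.10),
    )
    female_share: float = 0.51
    imd_shares: tuple = (0.2, 0.2, 0.2, 0.2, 0.2)  # quintile 5 = most deprived
    employment_rate: float = 0.563  # overall share employed at baseline
    retirement_age: int = 65
    metabolic_means: dict = field(
        default_factory=lambda: {"bmi": 27.3, "hba1c": 5.45, "sbp": 128.0, "total_chol": 5.2}
    )
    metabolic_sds: dict = field(
        default_factory=lambda: {"bmi": 4.8, "hba1c": 0.40, "sbp": 15.0, "total_chol": 1.1}
    )
    metabolic_corr: list = field(default_factory=_default_corr)
    # per-year-of-age shift of the mean, centred at age 45
    age_slopes: dict = field(
        default_factory=lambda: {"bmi": 0.03, "hba1c": 0.008, "sbp": 0.45, "total_chol": 0.012}
    )
    # additive shift per IMD quintile step above/below 3 (deprivation gradient)
    imd_gradient: dict = field(default_factory=lambda: {"bmi": 0.35, "hba1c": 0.02})
    smoker_shares: dict = field(
        default_factory=lambda: {"non": 0.55, "ex": 0.25, "current": 0.20}
    )
    ethnicity_shares: dict = field(
        default_factory=lambda: {"white": 0.86, "south_asian": 0.07, "black": 0.04, "other": 0.03}
    )
    family_history_prev: float = 0.15
    undiagnosed_diabetes_fraction: float = 0.02
    undiagnosed_hba1c_range: tuple = (6.5, 8.0)
    hba1c_baseline_range: tuple = (3.5, 6.4)
    bounds: dict = field(
        default_factory=lambda: {
            "bmi": (15.0, 60.0),
            "sbp": (80.0, 220.0),
            "total_chol": (2.0, 12.0),
        }
    )
    hdl_mean: dict = field(default_factory=lambda: {"male": 1.3, "female": 1.55})
    hdl_sd: float = 0.30
    eq5d_mean: float = 0.95
    eq5d_age_slope: float = 0.0015  # decrement per year of age over 40
    eq5d_sd: float = 0.08

    def validate(self) -> None:
        if not isinstance(self.n, (int, np.integer)) or self.n < 1:
            raise PopulationSpecError("n: must be an integer >= 1")
        for name, shares in (
            ("age_bands", [b[2] for b in self.age_bands]),
            ("imd_shares", list(self.imd_shares)),
            ("smoker_shares", list(self.smoker_shares.values())),
            ("ethnicity_shares", list(self.ethnicity_shares.values())),
        ):
            if any(s < 0 or s > 1 for s in shares):
                raise PopulationSpecError(f"{name}: proportions must lie in [0, 1]")
            if abs(sum(shares) - 1.0) > 1e-8:
                raise PopulationSpecError(f"{name}: proportions must sum to 1")
        for name, p in (
            ("female_share", self.female_share),
            ("employment_rate", self.employment_rate),
            ("family_history_prev", self.family_history_prev),
            ("undiagnosed_diabetes_fraction", self.undiagnosed_diabetes_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise PopulationSpecError(f"{name}: must lie in [0, 1]")
        corr = np.asarray(self.metabolic_corr, dtype=float)
        if corr.shape != (4, 4) or not np.allclose(corr, corr.T):
            raise PopulationSpecError("metabolic_corr: must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(corr).min() < -1e-9:
            raise PopulationSpecError("metabolic_corr: must be positive semi-definite")
        for f in METABOLIC_FACTORS:
            if self.metabolic_means.get(f, 0.0) <= 0:
                raise PopulationSpecError(f"metabolic_means[{f}]: must be strictly positive")
            if self.metabolic_sds.get(f, 0.0) < 0:
                raise PopulationSpecError(f"metabolic_sds[{f}]: must be non-negative")
        if any(a[0] < 16 for a in self.age_bands):
            raise PopulationSpecError("age_bands: minimum age is 16")


def generate_population(spec: PopulationSpec) -> pd.DataFrame:
    """Draw a cohort of `spec.n` individuals; deterministic given spec.seed.

    Nobody starts with a diabetes diagnosis; a configurable fraction starts
    with undiagnosed diabetes (HbA1c drawn above the diagnostic threshold).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n)

    band_idx = rng.choice(len(spec.age_bands), size=n, p=[b[2] for b in spec.age_bands])
    lo = np.array([b[0] for b in spec.age_bands])[band_idx]
    hi = np.array([b[1] for b in spec.age_bands])[band_idx]
    age = lo + rng.integers(0, hi - lo + 1, size=n)

    sex = np.where(rng.random(n) < spec.female_share, "female", "male")
    imd = rng.choice(np.arange(1, 6), size=n, p=list(spec.imd_shares))
    ethnicity = rng.choice(
        list(spec.ethnicity_shares), size=n, p=list(spec.ethnicity_shares.values())
    )
    smoker = rng.choice(list(spec.smoker_shares), size=n, p=list(spec.smoker_shares.values()))
    family_history = rng.random(n) < spec.family_history_prev

    # Employment confined to working ages, rescaled so the overall share
    # matches the target rate in expectation.
    under = age < spec.retirement_age
    p_under = max(under.mean(), 1e-12)
    employed = under & (rng.random(n) < min(1.0, spec.employment_rate / p_under))

    # Gaussian copula for the metabolic block
    corr = np.asarray(spec.metabolic_corr, dtype=float)
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(4))
    z = rng.standard_normal((n, 4)) @ chol.T
    vals = {}
    for j, f in enumerate(METABOLIC_FACTORS):
        mean = (
            spec.metabolic_means[f]
            + spec.age_slopes.get(f, 0.0) * (age - 45)
            + spec.imd_gradient.get(f, 0.0) * (imd - 3)
        )
        vals[f] = mean + spec.metabolic_sds[f] * z[:, j]
    for f, (blo, bhi) in spec.bounds.items():
        vals[f] = np.clip(vals[f], blo, bhi)
    vals["hba1c"] = np.clip(vals["hba1c"], *spec.hba1c_baseline_range)
    undiag = rng.random(n) < spec.undiagnosed_diabetes_fraction
    vals["hba1c"] = np.where(
        undiag, rng.uniform(*spec.undiagnosed_hba1c_range, size=n), vals["hba1c"]
    )

    hdl_mu = np.where(sex == "female", spec.hdl_mean["female"], spec.hdl_mean["male"])
    hdl = np.clip(hdl_mu + spec.hdl_sd * rng.standard_normal(n), 0.5, 3.5)

    eq5d = np.clip(
        spec.eq5d_mean
        - spec.eq5d_age_slope * np.maximum(age - 40, 0)
        + spec.eq5d_sd * rng.standard_normal(n),
        EQ5D_FLOOR,
        1.0,
    )

    df = pd.DataFrame(
        {
            "id": np.arange(n, dtype=np.int64),
            "age": age.astype(np.int64),
            "sex": sex,
            "ethnicity": ethnicity,
            "imd_quintile": imd.astype(np.int64),
            "employed": employed,
            "bmi": vals["bmi"],
            "hba1c": vals["hba1c"],
            "sbp": vals["sbp"],
            "total_chol": vals["total_chol"],
            "hdl_chol": hdl,
            "smoker": smoker,
            "family_history_diabetes": family_history,
            "eq5d_baseline": eq5d,
            "diagnosed_diabetes": np.zeros(n, dtype=bool),
            "diagnosed_hypertension": np.zeros(n, dtype=bool),
            "diagnosed_dyslipidaemia": np.zeros(n, dtype=bool),
            "diabetes_onset_year": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    for c in CONDITIONS:
        df[f"has_{c}"] = np.zeros(n, dtype=bool)
    df["alive"] = np.ones(n, dtype=bool)
    return df[list(COLUMNS)]


_BOOL_COLS = (
    "employed",
    "family_history_diabetes",
    "diagnosed_diabetes",
    "diagnosed_hypertension",
    "diagnosed_dyslipidaemia",
    "alive",
) + tuple(f"has_{c}" for c in CONDITIONS)


def validate_population(df: pd.DataFrame) -> None:
    """Raise on the first row violating an Individual invariant."""

    def bad(mask, msg):
        if mask.any():
            row = int(np.flatnonzero(np.asarray(mask))[0])
            raise PopulationValidationError(f"row {row}: {msg}")

    bad(df["age"] < 16, "age must be >= 16")
    bad(~df["imd_quintile"].isin([1, 2, 3, 4, 5]), "imd_quintile must be in 1..5")
    bad(~df["sex"].isin(SEXES), "sex must be male or female")
    bad(~df["smoker"].isin(SMOKER_STATES), "smoker must be one of non/ex/current")
    bad(~df["ethnicity"].isin(ETHNICITIES), f"ethnicity must be one of {ETHNICITIES}")
    for c in ("bmi", "hba1c", "sbp", "total_chol", "hdl_chol"):
        bad(df[c] <= 0, f"{c} must be strictly positive")
    bad(df["eq5d_baseline"] > 1.0, "eq5d_baseline must be <= 1")
    bad(df["eq5d_baseline"] < EQ5D_FLOOR, f"eq5d_baseline must be >= {EQ5D_FLOOR}")


def write_population(df: pd.DataFrame, path) -> None:
    """Write a cohort as UTF-8 CSV with the documented header ('.' decimal)."""
    df.to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    """Read and validate a cohort CSV; round-trips write_population exactly."""
    df = pd.read_csv(path, dtype={"diabetes_onset_year": "Int64"})
    missing = [c for c in COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in COLUMNS]
    if missing or extra:
        parts = []
        if missing:
            parts.append(f"missing columns: {missing}")
        if extra:
            parts.append(f"unexpected columns: {extra}")
        raise SchemaError("; ".join(parts))
    for c in _BOOL_COLS:
        if df[c].dtype != bool:
            df[c] = df[c].astype(bool)
    df["id"] = df["id"].astype(np.int64)
    df["age"] = df["age"].astype(np.int64)
    df["imd_quintile"] = df["imd_quintile"].astype(np.int64)
    validate_population(df)
    return df[list(COLUMNS)]
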