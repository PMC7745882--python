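"""Synthetic postmenopausal cohort with NHANES-like structure.

Generates a cohort of women aged 50-79 whose marginal distributions match a
DXA-surveyed US reference sample: age from a truncated normal law, three
race/ethnicity categories, BMI, femoral-neck BMD expressed as a T-score
whose mean declines linearly with age, and six binary clinical risk-factor
flags (drawn independently; the reference sample reports marginal
prevalences only, and a correlation hook is exposed for users who want a
joint law).

The ``age_mean_sd`` and ``tscore_mean_sd`` of a :class:`CohortSpec` are the
OBSERVED moments the generated cohort should reproduce.  Because truncation
to [50, 79] changes the moments of a normal law, the generator solves for
the parent-normal parameters whose truncated moments equal the requested
ones, and shrinks the residual T-score SD so that the age trend plus noise
reproduce the pooled T-score SD exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trajectory import DEFAULT_TSCORE_REF, TScoreReference, bmd_to_tscore, tscore_to_bmd

__all__ = [
    "RACE_CATEGORIES",
    "FLAG_COLUMNS",
    "COHORT_COLUMNS",
    "ASSUMED_HEIGHT_M",
    "Subject",
    "CohortSpec",
    "CohortValidationError",
    "generate_cohort",
    "summarize_cohort",
    "read_cohort",
    "write_cohort",
    "weight_kg",
    "NHANES_VARIABLE_MAP",
    "cohort_from_nhanes",
]

RACE_CATEGORIES = ("white", "black", "hispanic")

FLAG_COLUMNS = (
    "prior_fracture",
    "parental_fracture",
    "current_smoker",
    "glucocorticoid_use",
    "rheumatoid_arthritis",
    "heavy_alcohol",
)

COHORT_COLUMNS = ("id", "age", "race", "bmi", "fn_bmd") + FLAG_COLUMNS

#: Fixed height for the BMI -> weight conversion; weight is only needed for
#: risk-engine interfaces that take weight instead of BMI.
ASSUMED_HEIGHT_M = 1.60

# Reference-sample marginals: race from exact category counts (1339/507/457
# of 2303, which sum to 1 exactly), risk-factor prevalences as printed.
_DEFAULT_RACE_PROBS = {
    "white": 1339 / 2303,
    "black": 507 / 2303,
    "hispanic": 457 / 2303,
}
_DEFAULT_PREVALENCES = {
    "prior_fracture": 0.036,
    "parental_fracture": 0.217,
    "current_smoker": 0.168,
    "glucocorticoid_use": 0.046,
    "rheumatoid_arthritis": 0.094,
    "heavy_alcohol": 0.069,  # 2+ drinks/day, proxy for the 3+ units/day factor
}


class CohortValidationError(ValueError):
    """A cohort file or frame violates the documented schema."""


@dataclass(frozen=True)
class Subject:
    """One woman's risk-engine inputs.

    ``heavy_alcohol`` proxies the "3+ units/day" clinical risk factor using
    the 2+ drinks/day questionnaire item available in survey data.
    """

    id: object
    age: int
    race: str
    bmi: float
    fn_bmd: float
    prior_fracture: bool = False
    parental_fracture: bool = False
    current_smoker: bool = False
    glucocorticoid_use: bool = False
    rheumatoid_arthritis: bool = False
    heavy_alcohol: bool = False

    def __post_init__(self):
        if not (50 <= self.age <= 79):
            raise ValueError(f"age {self.age} outside [50, 79]")
        if self.race not in RACE_CATEGORIES:
            raise ValueError(
                f"race {self.race!r} not one of {RACE_CATEGORIES}"
            )
        if not (10 < self.bmi < 70):
            raise ValueError(f"bmi {self.bmi} outside (10, 70)")
        if not (0 < self.fn_bmd < 2.0):
            raise ValueError(f"fn_bmd {self.fn_bmd} outside (0, 2.0) g/cm^2")

    @property
    def weight(self) -> float:
        """Body weight in kg, derived from BMI at the assumed height."""
        return self.bmi * ASSUMED_HEIGHT_M**2

    def to_row(self) -> dict:
        return {c: getattr(self, c) for c in COHORT_COLUMNS}


@dataclass(frozen=True)
class CohortSpec:
    """Target marginal structure of a synthetic cohort.

    ``age_mean_sd`` and ``tscore_mean_sd`` are observed (post-truncation)
    moments.  ``tscore_age_slope`` is the linear decline of the mean T-score
    per year of age, centered at age 63; the residual SD is chosen so the
    pooled T-score SD matches the spec exactly.
    """

    n: int = 2303
    age_range: tuple = (50, 79)
    age_mean_sd: tuple = (63.0, 8.0)
    race_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RACE_PROBS)
    )
    bmi_mean_sd: tuple = (29.05, 5.99)
    tscore_mean_sd: tuple = (-0.96, 1.12)
    tscore_age_slope: float = -0.045
    risk_factor_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCES)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("cohort size n must be positive")
        lo, hi = self.age_range
        if not (lo < hi):
            raise ValueError("age_range must be increasing")
        if set(self.race_probs) != set(RACE_CATEGORIES):
            raise ValueError(f"race_probs must cover exactly {RACE_CATEGORIES}")
        total = sum(self.race_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"race_probs sum to {total}, expected 1 within 1e-9")
        if set(self.risk_factor_prevalences) != set(FLAG_COLUMNS):
            raise ValueError(f"risk_factor_prevalences must cover exactly {FLAG_COLUMNS}")
        for k, p in self.risk_factor_prevalences.items():
            if not (0 <= p <= 1):
                raise ValueError(f"prevalence of {k} = {p} outside [0, 1]")
        if self.age_mean_sd[1] <= 0 or self.bmi_mean_sd[1] <= 0 or self.tscore_mean_sd[1] <= 0:
            raise ValueError("scale parameters must be positive")


@lru_cache(maxsize=32)
def _truncnorm_parent(lo: float, hi: float, mean: float, sd: float) -> tuple[float, float]:
    """Parent N(m, s) whose truncation to [lo, hi] has the given moments."""

    def moments(x):
        m, log_s = x
        s = np.exp(log_s)
        a, b = (lo - m) / s, (hi - m) / s
        d = stats.truncnorm(a, b, loc=m, scale=s)
        return [d.mean() - mean, d.std() - sd]

    sol = optimize.root(moments, x0=[mean, np.log(sd * 1.5)], method="hybr")
    resid = np.abs(moments(sol.x)).max()
    if not sol.success or resid > 1e-8:
        raise ValueError(
            f"no truncated normal on [{lo}, {hi}] has mean {mean}, sd {sd} "
            f"(best residual {resid:.2e}); the SD may exceed the uniform limit"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def generate_cohort(
    spec: CohortSpec,
    ref: TScoreReference = DEFAULT_TSCORE_REF,
    flag_sampler: Callable | None = None,
) -> pd.DataFrame:
    """Draw a synthetic cohort; deterministic given ``spec.seed``.

    Ages are drawn from the truncated normal matching the observed moments
    and rounded to integers.  T-scores follow a linear-in-age mean with
    normal residuals, then convert to femoral-neck BMD against ``ref``.

    ``flag_sampler(rng, n, prevalences) -> DataFrame`` may replace the
    default independent draws to impose risk-factor correlation.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range
    mean_age, sd_age = spec.age_mean_sd
    m, s = _truncnorm_parent(float(lo), float(hi), float(mean_age), float(sd_age))
    a, b = (lo - m) / s, (hi - m) / s
    ages_cont = stats.truncnorm.rvs(a, b, loc=m, scale=s, size=spec.n, random_state=rng)
    ages = np.clip(np.rint(ages_cont), lo, hi).astype(int)

    races = rng.choice(
        RACE_CATEGORIES, size=spec.n, p=[spec.race_probs[r] for r in RACE_CATEGORIES]
    )

    bmi = rng.normal(spec.bmi_mean_sd[0], spec.bmi_mean_sd[1], size=spec.n)
    bmi = np.clip(bmi, 13.0, 55.0)

    # T-score: linear mean trend in age plus normal residual.  Rounding ages
    # to integers adds 1/12 to the age variance.
    ts_mean, ts_sd = spec.tscore_mean_sd
    age_var = sd_age**2 + 1.0 / 12.0
    resid_var = ts_sd**2 - spec.tscore_age_slope**2 * age_var
    if resid_var <= 0:
        raise ValueError(
            "tscore_age_slope explains more variance than the pooled T-score SD allows"
        )
    center = ts_mean - spec.tscore_age_slope * (mean_age - 63.0)
    tscores = (
        center
        + spec.tscore_age_slope * (ages - 63.0)
        + np.sqrt(resid_var) * rng.standard_normal(spec.n)
    )
    fn_bmd = np.clip(tscore_to_bmd(tscores, ref), 0.02, 1.99)

    if flag_sampler is None:
        flags = {
            f: rng.random(spec.n) < spec.risk_factor_prevalences[f]
            for f in FLAG_COLUMNS
        }
        flag_df = pd.DataFrame(flags)
    else:
        flag_df = flag_sampler(rng, spec.n, dict(spec.risk_factor_prevalences))
        if list(flag_df.columns) != list(FLAG_COLUMNS) or len(flag_df) != spec.n:
            raise ValueError("flag_sampler must return an (n, 6) frame with the flag columns")

    out = pd.DataFrame(
        {
            "id": np.arange(1, spec.n + 1),
            "age": ages,
            "race": races,
            "bmi": bmi,
            "fn_bmd": fn_bmd,
        }
    )
    for f in FLAG_COLUMNS:
        out[f] = flag_df[f].to_numpy(dtype=bool)
    return out


def weight_kg(cohort: pd.DataFrame) -> pd.Series:
    """Body weight derived from BMI at the assumed 1.60 m height."""
    return cohort["bmi"] * ASSUMED_HEIGHT_M**2


def summarize_cohort(
    cohort: pd.DataFrame, ref: TScoreReference = DEFAULT_TSCORE_REF
) -> pd.DataFrame:
    """Tidy characteristics table: one row per (variable, statistic)."""
    if len(cohort) == 0:
        raise ValueError("cannot summarize an empty cohort")
    rows: list[tuple] = [("n", "count", float(len(cohort)))]

    def moments(name, x):
        rows.extend(
            [
                (name, "mean", float(np.mean(x))),
                (name, "sd", float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
                (name, "median", float(np.median(x))),
                (name, "min", float(np.min(x))),
                (name, "max", float(np.max(x))),
            ]
        )

    moments("age", cohort["age"].to_numpy(dtype=float))
    for race in RACE_CATEGORIES:
        k = int((cohort["race"] == race).sum())
        rows.append((f"race_{race}", "count", float(k)))
        rows.append((f"race_{race}", "percent", 100.0 * k / len(cohort)))
    moments("bmi", cohort["bmi"].to_numpy(dtype=float))
    moments("tscore", bmd_to_tscore(cohort["fn_bmd"].to_numpy(dtype=float), ref))
    for f in FLAG_COLUMNS:
        k = int(cohort[f].sum())
        rows.append((f, "count", float(k)))
        rows.append((f, "percent", 100.0 * k / len(cohort)))
    return pd.DataFrame(rows, columns=["variable", "statistic", "value"])


# ---------------------------------------------------------------------------
# Delimited-file round trip
# ---------------------------------------------------------------------------


def _validate_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise CohortValidationError(
            f"{source}: missing columns {sorted(missing)}"
        )
    df = df[list(COHORT_COLUMNS)].copy()
    checks = [
        ("age", lambda v: (v >= 50) & (v <= 79), "age outside [50, 79]"),
        ("race", lambda v: v.isin(RACE_CATEGORIES),
         f"race not in {list(RACE_CATEGORIES)}"),
        ("bmi", lambda v: (v > 10) & (v < 70), "bmi outside (10, 70)"),
        ("fn_bmd", lambda v: (v > 0) & (v < 2.0), "fn_bmd outside (0, 2.0)"),
    ]
    for col, ok_fn, msg in checks:
        ok = ok_fn(df[col])
        if not ok.all():
            row = int(np.flatnonzero(~ok.to_numpy())[0])
            raise CohortValidationError(
                f"{source}: row {row}, field {col!r}: {msg} "
                f"(value {df[col].iloc[row]!r})"
            )
    for f in FLAG_COLUMNS:
        vals = df[f]
        if not vals.isin([0, 1, True, False]).all():
            row = int(np.flatnonzero(~vals.isin([0, 1, True, False]).to_numpy())[0])
            raise CohortValidationError(
                f"{source}: row {row}, field {f!r}: flags must be 0/1 "
                f"(value {vals.iloc[row]!r})"
            )
        df[f] = vals.astype(bool)
    df["age"] = df["age"].astype(int)
    return df


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a delimited cohort file (``.tsv`` => tab)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    return _validate_frame(df, str(path))


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort; flags as 0/1, reals at full precision (exact round trip)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    out = cohort[list(COHORT_COLUMNS)].copy()
    for f in FLAG_COLUMNS:
        out[f] = out[f].astype(int)
    path.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Optional NHANES ingestion (documented mapping; untested in CI — requires
# user-supplied XPT extracts loaded into pandas, e.g. via pyreadstat)
# ---------------------------------------------------------------------------

#: Mapping from NHANES variable names to cohort fields.  The user joins the
#: DXA, demographic, and questionnaire files on SEQN, derives the flags, and
#: renames columns per this map before calling :func:`cohort_from_nhanes`.
NHANES_VARIABLE_MAP = {
    "SEQN": "id",
    "RIDAGEYR": "age",
    "RIDRETH1": "race",  # recode: 3 -> white, 4 -> black, 1/2 -> hispanic
    "BMXBMI": "bmi",
    "DXXNKBMD": "fn_bmd",  # femoral-neck BMD, g/cm^2 (Hologic)
    # flags derived from OSQ (fracture/parental history), SMQ (smoking),
    # RXQ/OSQ (glucocorticoids), MCQ (arthritis type), ALQ (drinks/day >= 2)
}


def cohort_from_nhanes(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a user-prepared NHANES extract as a cohort frame.

    Optional convenience: the caller performs the join/recode described in
    :data:`NHANES_VARIABLE_MAP`; this function only renames mapped columns
    that are still present and applies the standard validation.
    """
    df = frame.rename(columns={k: v for k, v in NHANES_VARIABLE_MAP.items() if k in frame})
    return _validate_frame(df, "NHANES extract")
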