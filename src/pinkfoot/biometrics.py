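"""Body size and condition of captured geese.

Expected mass is predicted from a sex-specific OLS of mass on wing length
(wing chosen as the size measure because mass-wing regressions explain more
variance than mass-head ones), and body condition is the dimensionless
ratio mass / expected mass — values above 1 indicate more body stores than
a typical goose of that size. Route and sex comparisons of size and
condition run as linear mixed models with a random intercept of year,
mass and condition linearly corrected for capture date.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats import MixedFit, MixedModelSpec, fit_mixed

# validation bounds for adult pink-footed geese (ingest-time rejection)
HEAD_MM = (80.0, 120.0)
WING_MM = (350.0, 520.0)
MASS_G = (1500.0, 4500.0)


@dataclass
class AllometryFit:
    sex: str
    intercept: float
    slope: float          # g per mm wing
    r2: float
    n: int


@dataclass
class ConditionRecord:
    animal_id: str
    condition: float
    expected_mass_g: float

    def __post_init__(self):
        if self.condition <= 0:
            raise ValueError("condition must be positive")


def validate_captures(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split captures into (valid, rejected-with-reason) by biometric range."""
    r = records.copy()
    reasons = pd.Series("", index=r.index)
    for col, (lo, hi), label in [("head_mm", HEAD_MM, "head"), ("wing_mm", WING_MM, "wing"),
                                 ("mass_g", MASS_G, "mass")]:
        bad = ~r[col].between(lo, hi)
        reasons[bad] += f"{label} out of [{lo}, {hi}]; "
    rejected = r[reasons != ""].assign(reason=reasons[reasons != ""].str.strip())
    return r[reasons == ""], rejected


def fit_allometry(records: pd.DataFrame, sex: str, min_n: int = 10) -> AllometryFit:
    """Sex-specific OLS of body mass on wing length (pooled across routes)."""
    sub = records[records["sex"] == sex]
    if len(sub) < min_n:
        raise ValueError(f"need >= {min_n} records of sex {sex!r}, got {len(sub)}")
    X = sm.add_constant(sub["wing_mm"].to_numpy(dtype=float))
    fit = sm.OLS(sub["mass_g"].to_numpy(dtype=float), X).fit()
    return AllometryFit(sex=sex, intercept=float(fit.params[0]), slope=float(fit.params[1]),
                        r2=float(fit.rsquared), n=len(sub))


def body_condition(record: pd.Series, fit: AllometryFit) -> ConditionRecord:
    """Observed mass divided by the allometric expectation for its wing length."""
    if record["sex"] != fit.sex:
        raise ValueError(f"record sex {record['sex']!r} does not match fit sex {fit.sex!r}")
    expected = fit.intercept + fit.slope * float(record["wing_mm"])
    if expected <= 0:
        raise ValueError("non-positive expected mass")
    return ConditionRecord(str(record["animal_id"]), float(record["mass_g"]) / expected, expected)


def condition_table(records: pd.DataFrame, fits: dict[str, AllometryFit] | None = None) -> pd.DataFrame:
    """Per-capture condition; allometry fitted per sex on the records unless given."""
    fits = fits or {s: fit_allometry(records, s) for s in records["sex"].unique()}
    out = records.copy()
    expected = np.array([fits[s].intercept + fits[s].slope * w
                         for s, w in zip(out["sex"], out["wing_mm"])])
    out["expected_mass_g"] = expected
    out["condition"] = out["mass_g"].to_numpy(dtype=float) / expected
    return out


def compare_routes(records: pd.DataFrame) -> dict[str, MixedFit]:
    """Route/sex comparisons of head, wing, mass and condition (LMM, year intercept).

    Mass and condition include a capture-date covariate (day of year,
    centered at the sample mean); condition additionally tests a
    route-by-sex interaction.
    """
    for col in ("route", "sex", "year", "day_of_year"):
        if col not in records:
            raise ValueError(f"missing column {col!r}")
    if records["route"].nunique() < 2:
        raise ValueError("both routes required for a comparison")
    if records["sex"].nunique() < 2:
        raise ValueError("both sexes required for a comparison")
    d = condition_table(records)
    d["doy_c"] = d["day_of_year"] - d["day_of_year"].mean()
    out = {}
    for resp in ("head_mm", "wing_mm"):
        spec = MixedModelSpec(resp, "C(route) + C(sex)", groups=("year",), family="gaussian")
        out[resp] = fit_mixed(spec, d)
    out["mass_g"] = fit_mixed(
        MixedModelSpec("mass_g", "C(route) + C(sex) + doy_c", groups=("year",)), d)
    out["condition"] = fit_mixed(
        MixedModelSpec("condition", "C(route) * C(sex) + doy_c", groups=("year",)), d)
    return out
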