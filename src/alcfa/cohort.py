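"""Participant-level cohort handling: exclusions, transforms, covariate
adjustment, and the bridge to the covariance matrix the factor models analyze.

A cohort is a pandas DataFrame with one row per participant.  Canonical
indicator columns (raw units):

    sbp (mmHg), dbp (mmHg), bmi (kg/m2), waist (inches), glucose (mg/dl),
    insulin (uU/ml), hdl (mg/dl), triglycerides (mg/dl), il6 (pg/ml),
    crp (mg/L), hf_hrv_paced / hf_hrv_unpaced (ms2),
    rmssd_paced / rmssd_unpaced (ms)

Covariates: age (years), sex ({male, female}), race ({european_american,
african_american}).  Medication-use flags are boolean columns (med_*).
Missing values are NaN (read from CSV as empty fields or "NA").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "INDICATORS",
    "COVARIATES",
    "MEDICATION_FLAGS",
    "DEFAULT_TRANSFORMS",
    "ExclusionCriteria",
    "DEFAULT_EXCLUSIONS",
    "apply_exclusions",
    "transform_variables",
    "adjust_covariates",
    "sample_covariance",
    "rmssd",
    "descriptives",
    "read_cohort",
    "write_cohort",
]

from .cfa import CovarianceInput

METABOLIC_INDICATORS = (
    "insulin",
    "glucose",
    "bmi",
    "waist",
    "hdl",
    "triglycerides",
    "sbp",
    "dbp",
)
INDICATORS = METABOLIC_INDICATORS + (
    "il6",
    "crp",
    "hf_hrv_paced",
    "rmssd_paced",
    "hf_hrv_unpaced",
    "rmssd_unpaced",
)
COVARIATES = ("age", "sex", "race")
MEDICATION_FLAGS = (
    "med_antihypertensive",
    "med_hypoglycemic",
    "med_cholesterol",
    "med_immunosuppressant",
    "med_cold",
    "med_antibiotic",
)

#: transform applied to each variable before analysis; natural log for the
#: right-skewed markers, reciprocal for IL-6, identity otherwise
DEFAULT_TRANSFORMS: dict[str, str] = {
    **{v: "identity" for v in INDICATORS},
    "crp": "natural_log",
    "insulin": "natural_log",
    "glucose": "natural_log",
    "triglycerides": "natural_log",
    "rmssd_paced": "natural_log",
    "rmssd_unpaced": "natural_log",
    "hf_hrv_paced": "natural_log",
    "hf_hrv_unpaced": "natural_log",
    "il6": "reciprocal",
}

_TRANSFORM_FUNCS = {
    "identity": lambda x: x,
    "natural_log": np.log,
    "reciprocal": lambda x: 1.0 / x,
}


class CohortConfigError(ValueError):
    """Criteria or column configuration inconsistent with the cohort."""


class CohortDataError(ValueError):
    """A data value violates a transform or adjustment precondition."""


@dataclass(frozen=True)
class ExclusionCriteria:
    """Participant exclusion rules, applied in a fixed order.

    Rules are applied sequentially -- medication use first, then the acute-
    inflammation biomarker thresholds (values strictly greater than the
    threshold are excluded), then completeness of the required variables --
    and each excluded participant is tallied once, at the first rule violated.
    """

    medication_flags_to_exclude: tuple[str, ...] = MEDICATION_FLAGS
    il6_max: float = 10.0  # pg/ml
    crp_max: float = 10.0  # mg/L
    require_complete: tuple[str, ...] = METABOLIC_INDICATORS

    def __post_init__(self):
        if self.il6_max <= 0 or self.crp_max <= 0:
            raise CohortConfigError("biomarker thresholds must be strictly positive")


DEFAULT_EXCLUSIONS = ExclusionCriteria()


def apply_exclusions(
    cohort: pd.DataFrame, criteria: ExclusionCriteria = DEFAULT_EXCLUSIONS
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop participants violating the exclusion rules; tally drops per rule.

    Returns the retained cohort (original row order) and a dict mapping rule
    name -> number of participants removed by that rule, in application order:
    each medication flag, then ``il6_crp``, then ``incomplete``.
    """
    for col in criteria.medication_flags_to_exclude:
        if col not in cohort.columns:
            raise CohortConfigError(f"medication flag column {col!r} not in cohort")
    for col in ("il6", "crp"):
        if col not in cohort.columns:
            raise CohortConfigError(f"biomarker column {col!r} not in cohort")
    for col in criteria.require_complete:
        if col not in cohort.columns:
            raise CohortConfigError(f"required-complete column {col!r} not in cohort")

    remaining = cohort
    tally: dict[str, int] = {}
    for flag in criteria.medication_flags_to_exclude:
        hit = remaining[flag].fillna(False).astype(bool)
        tally[flag] = int(hit.sum())
        remaining = remaining[~hit]
    hit = (remaining["il6"] > criteria.il6_max) | (remaining["crp"] > criteria.crp_max)
    hit = hit.fillna(False)
    tally["il6_crp"] = int(hit.sum())
    remaining = remaining[~hit]
    if criteria.require_complete:
        hit = remaining[list(criteria.require_complete)].isna().any(axis=1)
        tally["incomplete"] = int(hit.sum())
        remaining = remaining[~hit]
    else:
        tally["incomplete"] = 0
    return remaining.copy(), tally


def transform_variables(
    cohort: pd.DataFrame, transform_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Apply the per-variable normalizing transforms; missing stays missing.

    Log and reciprocal transforms require strictly positive values; a
    violation raises :class:`CohortDataError` naming the participant row and
    variable.
    """
    if transform_map is None:
        transform_map = DEFAULT_TRANSFORMS
    out = cohort.copy()
    for var, tname in transform_map.items():
        if var not in out.columns:
            continue
        if tname not in _TRANSFORM_FUNCS:
            raise CohortConfigError(f"unknown transform {tname!r} for {var!r}")
        col = out[var].astype(float)
        if tname in ("natural_log", "reciprocal"):
            bad = col[col.notna() & (col <= 0)]
            if len(bad):
                raise CohortDataError(
                    f"non-positive value for {tname} transform of {var!r} at "
                    f"participant {bad.index[0]}: {bad.iloc[0]}"
                )
        out[var] = _TRANSFORM_FUNCS[tname](col)
    return out


def adjust_covariates(
    cohort: pd.DataFrame,
    covariates: list[str] = list(COVARIATES),
    variables: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Residualize each indicator on an intercept plus the covariates.

    Categorical covariates (sex, race) are dummy-coded; numeric covariates
    enter linearly.  Each indicator column is replaced by its OLS residual,
    fitted on that column's non-missing rows (missing values stay missing).
    An empty covariate list centers each variable to mean zero.
    """
    if variables is None:
        variables = tuple(v for v in INDICATORS if v in cohort.columns)
    out = cohort.copy()
    n = len(out)
    design_cols = [np.ones(n)]
    for cov in covariates:
        if cov not in out.columns:
            raise CohortConfigError(f"covariate {cov!r} not in cohort")
        col = out[cov]
        if col.isna().any():
            raise CohortDataError(f"covariate {cov!r} has missing values")
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            design_cols.extend(dummies[c].to_numpy() for c in dummies.columns)
        else:
            design_cols.append(col.to_numpy(dtype=float))
    X = np.column_stack(design_cols)
    if n < X.shape[1] + len(variables) + 1:
        raise CohortDataError("too few participants for covariate adjustment")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CohortDataError("covariate design matrix is rank deficient")

    for var in variables:
        y = out[var].to_numpy(dtype=float)
        obs = np.isfinite(y)
        if obs.sum() <= X.shape[1]:
            raise CohortDataError(f"too few observed values to adjust {var!r}")
        beta, *_ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
        resid = np.full(n, np.nan)
        resid[obs] = y[obs] - X[obs] @ beta
        out[var] = resid
    return out


def sample_covariance(
    cohort: pd.DataFrame, variables: list[str] | tuple[str, ...]
) -> CovarianceInput:
    """Unbiased (N-1) covariance after listwise deletion on ``variables``."""
    missing = [v for v in variables if v not in cohort.columns]
    if missing:
        raise CohortConfigError(f"variables not in cohort: {missing}")
    sub = cohort[list(variables)].dropna()
    n, p = sub.shape
    if n <= p:
        raise CohortDataError(
            f"only {n} complete participants for {p} variables: covariance singular"
        )
    S = sub.cov().to_numpy()
    return CovarianceInput(S=S, N=n, names=tuple(variables))


def rmssd(ibi_series) -> float:
    """Root mean square of successive differences of interbeat intervals (ms).

    A time-domain index of cardiac vagal tone: sqrt(mean((ibi[t+1]-ibi[t])^2)).
    """
    x = np.asarray(ibi_series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("RMSSD requires a 1-d series of length >= 2")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise ValueError("interbeat intervals must be finite and positive")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))


def descriptives(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean/SD for numeric variables, category percentages for the rest."""
    if len(cohort) == 0:
        raise CohortDataError("cohort is empty")
    rows = []
    for col in cohort.columns:
        s = cohort[col]
        if pd.api.types.is_bool_dtype(s):
            rows.append({"variable": col, "statistic": "percent_true",
                         "value": 100.0 * s.fillna(False).mean()})
        elif pd.api.types.is_numeric_dtype(s):
            rows.append({"variable": col, "statistic": "mean", "value": s.mean()})
            rows.append({"variable": col, "statistic": "sd", "value": s.std(ddof=1)})
        else:
            freq = s.value_counts(normalize=True, dropna=True)
            for level, frac in freq.items():
                rows.append({"variable": col, "statistic": f"percent_{level}",
                             "value": 100.0 * frac})
    return pd.DataFrame(rows, columns=["variable", "statistic", "value"])


def read_cohort(path) -> pd.DataFrame:
    """Read a participant-per-row CSV; empty fields and "NA" are missing."""
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    for flag in MEDICATION_FLAGS:
        if flag in df.columns:
            df[flag] = df[flag].fillna(False).astype(bool)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV deterministically (missing as empty fields)."""
    cohort.to_csv(path, index=False, float_format="%.10g", na_rep="")


def write_covariance(data: CovarianceInput, path) -> None:
    """Covariance matrix as labelled CSV."""
    pd.DataFrame(data.S, index=list(data.names), columns=list(data.names)).to_csv(path)


def write_tally(tally: dict[str, int], path) -> None:
    with open(path, "w") as fh:
        json.dump(tally, fh, indent=2, sort_keys=False)
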