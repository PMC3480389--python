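"""Model-fit statistics and the nested-model chi-square difference test.

Three descriptive fit indices accompany the chi-square test: the comparative
fit index (CFI, improvement in noncentrality over an independence baseline;
>= 0.95 good), the root mean square error of approximation (RMSEA, per-df
noncentrality scaled by sample size; <= 0.05 good), and the average absolute
standardized residual (AASR; <= 0.05 good).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .cfa import FitResult, baseline_model, CovarianceInput

__all__ = [
    "FitIndices",
    "NestedComparison",
    "rmsea",
    "cfi",
    "avg_abs_std_residual",
    "chi_square_difference",
    "compute_fit_indices",
    "fit_table",
]


@dataclass(frozen=True)
class FitIndices:
    model: str
    chi_square: float
    df: int
    p_value: float
    cfi: float
    aasr: float
    rmsea: float


@dataclass(frozen=True)
class NestedComparison:
    restricted: str
    full: str
    delta_chi_square: float
    delta_df: int
    p_value: float
    better_model: str


def rmsea(chi_square: float, df: int, N: int) -> float:
    """sqrt(max(chi2 - df, 0) / (df * (N - 1)))."""
    if df < 1:
        raise ValueError("RMSEA is undefined for df = 0")
    if N < 2:
        raise ValueError("RMSEA requires N >= 2")
    return float(np.sqrt(max(chi_square - df, 0.0) / (df * (N - 1))))


def cfi(chi_square: float, df: int, chi_square_baseline: float, df_baseline: int) -> float:
    """Comparative fit index relative to the independence baseline."""
    d_m = max(chi_square - df, 0.0)
    d_b = max(chi_square_baseline - df_baseline, d_m, 0.0)
    if d_b == 0.0:
        return 1.0
    return float(1.0 - d_m / d_b)


def avg_abs_std_residual(
    S: np.ndarray, Sigma: np.ndarray, *, include_diagonal: bool = True
) -> float:
    """Mean |(s_ij - sigma_ij) / sqrt(s_ii s_jj)| over unique elements.

    Averaging includes the diagonal by default (the EQS convention);
    ``include_diagonal=False`` restricts to the off-diagonal elements.
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if S.shape != Sigma.shape:
        raise ValueError("S and Sigma must have the same shape")
    d = np.diag(S)
    if np.any(d <= 0):
        raise ValueError("S must have a strictly positive diagonal")
    scale = np.sqrt(np.outer(d, d))
    resid = np.abs(S - Sigma) / scale
    iu = np.triu_indices(S.shape[0], k=0 if include_diagonal else 1)
    return float(np.mean(resid[iu]))


def chi_square_difference(fit_restricted: FitResult, fit_full: FitResult) -> NestedComparison:
    """Likelihood-ratio test between nested fits on the same data.

    The restricted model must have strictly more degrees of freedom; the
    difference in chi-square is referred to a central chi-square with
    delta-df degrees of freedom.  A materially negative difference (the full
    model fitting worse than its restriction by more than optimizer noise)
    triggers a warning.
    """
    if fit_restricted.N != fit_full.N:
        raise ValueError("nested comparison requires the same sample (N differs)")
    if fit_restricted.spec is not None and fit_full.spec is not None:
        if fit_restricted.spec.indicators != fit_full.spec.indicators:
            raise ValueError("nested comparison requires the same variable set")
    delta_df = fit_restricted.df - fit_full.df
    if delta_df < 1:
        raise ValueError("models are not nested: restricted df must exceed full df")
    raw = fit_restricted.chi_square - fit_full.chi_square
    if raw < -1e-4:
        warnings.warn(
            f"restricted model fits better than the full model (delta chi2 = {raw:.3g}); "
            "check convergence",
            RuntimeWarning,
            stacklevel=2,
        )
    delta = max(raw, 0.0)
    p = float(scipy.stats.chi2.sf(delta, delta_df))
    better = fit_full.model if p < 0.05 else fit_restricted.model
    return NestedComparison(
        restricted=fit_restricted.model,
        full=fit_full.model,
        delta_chi_square=float(delta),
        delta_df=int(delta_df),
        p_value=p,
        better_model=better,
    )


def compute_fit_indices(
    fit: FitResult,
    data: CovarianceInput,
    baseline: FitResult | None = None,
) -> FitIndices:
    """Assemble the full fit-statistic row for one fitted model."""
    sub = data.subset(fit.spec.indicators) if fit.spec is not None else data
    if baseline is None:
        baseline = baseline_model(sub)
    return FitIndices(
        model=fit.model,
        chi_square=fit.chi_square,
        df=fit.df,
        p_value=fit.p_value,
        cfi=cfi(fit.chi_square, fit.df, baseline.chi_square, baseline.df),
        aasr=avg_abs_std_residual(sub.S, fit.implied),
        rmsea=rmsea(fit.chi_square, fit.df, fit.N) if fit.df > 0 else 0.0,
    )


def fit_table(rows: list[FitIndices]) -> pd.DataFrame:
    """One row per model, fixed column order, full precision."""
    return pd.DataFrame(
        [
            {
                "model": r.model,
                "chi_square": r.chi_square,
                "df": r.df,
                "p_value": r.p_value,
                "cfi": r.cfi,
                "aasr": r.aasr,
                "rmsea": r.rmsea,
            }
            for r in rows
        ],
        columns=["model", "chi_square", "df", "p_value", "cfi", "aasr", "rmsea"],
    )
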