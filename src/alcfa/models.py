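"""The study's hierarchical factor models and the ordered comparison plan.

Five models over the allostatic-load indicator battery:

* ``model1_ms`` -- metabolic syndrome only: insulin resistance, adiposity,
  dyslipidemia and blood-pressure first-order factors under a single
  second-order MS factor (8 indicators).
* ``model2_al`` -- adds inflammation (IL-6, CRP) and vagal tone (HFHRV,
  RMSSD) first-order factors; all six load on a single second-order
  allostatic-load factor (12 indicators).
* ``model3_two_factor`` -- two orthogonal second-order factors: AL receiving
  all six first-order factors, MS receiving the four metabolic ones.
* ``model4_inflammation_only`` -- Model 3 with the vagal -> AL edge removed,
  so the AL-specific content reduces to inflammation.
* ``model5_vagal_only`` -- Model 3 with the inflammation -> AL edge removed.

Models 2, 4 and 5 are nested restrictions of Model 3 and are compared to it
by chi-square difference tests.  The ``paced``/``unpaced`` variant selects
which pair of heart-rate-variability columns defines the vagal factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cfa import CovarianceInput, FitResult, ModelSpec, FactorSpec, SecondOrderSpec, fit_model, baseline_model
from .indices import FitIndices, NestedComparison, chi_square_difference, compute_fit_indices, fit_table

__all__ = [
    "MODEL_NAMES",
    "build_model",
    "is_nested",
    "StudyPlan",
    "StudyReport",
    "default_plan",
    "run_study",
]

MODEL_NAMES = (
    "model1_ms",
    "model2_al",
    "model3_two_factor",
    "model4_inflammation_only",
    "model5_vagal_only",
)

_METABOLIC_FACTORS = ("insulin_resistance", "adiposity", "dyslipidemia", "blood_pressure")


def _first_order_factors(variant: str) -> tuple[FactorSpec, ...]:
    if variant not in ("paced", "unpaced"):
        raise ValueError(f"unknown respiration variant {variant!r}")
    hf = f"hf_hrv_{variant}"
    rm = f"rmssd_{variant}"
    return (
        FactorSpec("insulin_resistance", ("insulin", "glucose")),
        FactorSpec("adiposity", ("bmi", "waist")),
        # HDL runs against the dyslipidemia risk direction
        FactorSpec("dyslipidemia", ("hdl", "triglycerides"), anchor_sign=-1),
        FactorSpec("blood_pressure", ("sbp", "dbp")),
        # reciprocal-transformed IL-6 runs against the inflammation direction
        FactorSpec("inflammation", ("il6", "crp"), anchor_sign=-1),
        FactorSpec("vagal_tone", (hf, rm)),
    )


def build_model(name: str, variant: str = "paced") -> ModelSpec:
    """Return one of the study's models as a declarative :class:`ModelSpec`."""
    factors = _first_order_factors(variant)
    metabolic = factors[:4]
    all_names = tuple(f.name for f in factors)
    if name == "model1_ms":
        return ModelSpec(
            name=f"{name}_{variant}" if variant != "paced" else name,
            first_order=metabolic,
            second_order=(SecondOrderSpec("metabolic_syndrome", _METABOLIC_FACTORS),),
        )
    if name == "model2_al":
        second = (SecondOrderSpec("allostatic_load", all_names),)
    elif name == "model3_two_factor":
        second = (
            SecondOrderSpec("allostatic_load", all_names),
            SecondOrderSpec("metabolic_syndrome", _METABOLIC_FACTORS),
        )
    elif name == "model4_inflammation_only":
        second = (
            SecondOrderSpec("allostatic_load", _METABOLIC_FACTORS + ("inflammation",)),
            SecondOrderSpec("metabolic_syndrome", _METABOLIC_FACTORS),
        )
    elif name == "model5_vagal_only":
        second = (
            SecondOrderSpec("allostatic_load", _METABOLIC_FACTORS + ("vagal_tone",)),
            SecondOrderSpec("metabolic_syndrome", _METABOLIC_FACTORS),
        )
    else:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    return ModelSpec(
        name=f"{name}_{variant}" if variant != "paced" else name,
        first_order=factors,
        second_order=second,
    )


def is_nested(restricted: ModelSpec, full: ModelSpec) -> bool:
    """True when the restricted model's free parameters are a subset of the
    full model's (same indicator battery, fewer or equal edges)."""
    return (
        restricted.indicators == full.indicators
        and restricted.free_parameter_labels() < full.free_parameter_labels()
    )


@dataclass(frozen=True)
class StudyPlan:
    """Ordered models to fit plus the nested pairs to compare."""

    models: tuple[str, ...] = MODEL_NAMES
    comparisons: tuple[tuple[str, str], ...] = (
        ("model2_al", "model3_two_factor"),
        ("model4_inflammation_only", "model3_two_factor"),
        ("model5_vagal_only", "model3_two_factor"),
    )
    respiration_variant: str = "paced"

    def __post_init__(self):
        for restricted, full in self.comparisons:
            r = build_model(restricted, self.respiration_variant)
            f = build_model(full, self.respiration_variant)
            if not is_nested(r, f):
                raise ValueError(f"comparison pair not nested: {restricted} vs {full}")


def default_plan(variant: str = "paced") -> StudyPlan:
    return StudyPlan(respiration_variant=variant)


@dataclass
class StudyReport:
    fits: dict[str, FitResult]
    indices: pd.DataFrame
    comparisons: pd.DataFrame
    exclusion_tally: dict[str, int] | None = None
    notes: list[str] = field(default_factory=list)


def _label(name: str, variant: str) -> str:
    return f"{name}_{variant}" if variant != "paced" else name


def run_study(
    plan: StudyPlan,
    data: pd.DataFrame | CovarianceInput,
    *,
    preprocess: bool = True,
    seed: int = 0,
) -> StudyReport:
    """Fit every model in the plan, compute fit indices, run the comparisons.

    ``data`` may be a raw participant cohort (DataFrame; exclusions,
    transforms and covariate adjustment are then applied) or a ready
    :class:`CovarianceInput`.  Each model uses listwise-complete participants
    for its own variable set, so the unpaced variant's N shrinks
    automatically when unpaced recordings are missing.
    """
    variant = plan.respiration_variant
    tally = None
    notes: list[str] = []

    if isinstance(data, pd.DataFrame):
        cohort = data
        if preprocess:
            cohort, tally = cohort_mod.apply_exclusions(cohort)
            cohort = cohort_mod.transform_variables(cohort)
            covs = [c for c in cohort_mod.COVARIATES if c in cohort.columns]
            cohort = cohort_mod.adjust_covariates(cohort, covs)

        def cov_for(spec: ModelSpec) -> CovarianceInput:
            return cohort_mod.sample_covariance(cohort, list(spec.indicators))

    else:

        def cov_for(spec: ModelSpec) -> CovarianceInput:
            return data.subset(spec.indicators)

    fits: dict[str, FitResult] = {}
    rows: list[FitIndices] = []
    for name in plan.models:
        spec = build_model(name, variant)
        cov = cov_for(spec)
        fit = fit_model(spec, cov, seed=seed)
        fits[name] = fit
        if fit.converged:
            rows.append(compute_fit_indices(fit, cov, baseline_model(cov)))
        else:
            notes.append(f"{spec.name}: did not converge; fit indices suppressed")

    comp_rows = []
    for restricted, full in plan.comparisons:
        if restricted not in fits or full not in fits:
            continue
        fr, ff = fits[restricted], fits[full]
        if not (fr.converged and ff.converged):
            notes.append(
                f"comparison {restricted} vs {full} skipped: non-converged model"
            )
            continue
        comp = chi_square_difference(fr, ff)
        comp_rows.append(
            {
                "restricted": comp.restricted,
                "full": comp.full,
                "delta_chi_square": comp.delta_chi_square,
                "delta_df": comp.delta_df,
                "p_value": comp.p_value,
                "better_model": comp.better_model,
            }
        )

    return StudyReport(
        fits=fits,
        indices=fit_table(rows),
        comparisons=pd.DataFrame(
            comp_rows,
            columns=[
                "restricted",
                "full",
                "delta_chi_square",
                "delta_df",
                "p_value",
                "better_model",
            ],
        ),
        exclusion_tally=tally,
        notes=notes,
    )
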