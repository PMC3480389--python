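# Methods

## Model and estimation

`alcfa` fits second-order confirmatory factor models to a sample covariance
matrix `S` by Wishart maximum likelihood. A model is declared as a
`ModelSpec`: an ordered set of first-order factors, each owning a disjoint
set of observed indicators, plus zero or more second-order factors, each
receiving edges from a subset of the first-order factors (cross-loadings
allowed). The implied covariance is

    Σ(θ) = Λ (Γ Γ' + Ψ) Λ' + Θ

with second-order factors standardized (unit variances, zero covariances).
Identification follows the free-loading convention of classical hierarchical
EQS-style analyses: every indicator loading, second-order loading,
disturbance variance and unique variance is free, which makes the
parameter-count arithmetic reproduce the dfs conventionally reported for
this model family (Model 1: 36 − 24 = 12; Model 2: 78 − 36 = 42; Model 3:
78 − 40 = 38; Models 4/5: 78 − 39 = 39). For a model with no second-order
layer, first-order factor variances are fixed to 1 instead.

The discrepancy `F(S, Σ) = ln|Σ| − ln|S| + tr(S Σ⁻¹) − p` is minimized with
L-BFGS-B using the analytic gradient `dF = tr[Σ⁻¹(Σ − S)Σ⁻¹ dΣ]`. Because
`F` is invariant to per-variable rescaling for this model family (loadings
and uniquenesses absorb scale), optimization runs on the correlation matrix
and parameters are mapped back to the covariance scale afterwards; this
conditions the problem when indicator variances span orders of magnitude
(log HF power has variance ~0.004, log insulin ~0.24). Variances are
bounded below at 1e-6; estimates at that floor are flagged as Heywood cases
in the result rather than silently accepted. Convergence uses relative-F
and gradient tolerances (ftol 1e-12, gtol 1e-8); on failure the
deterministic start is jittered with a seeded RNG for up to 10 restarts.
Start values: loadings `sqrt(s_ii/2)`, uniquenesses `s_ii/2`, disturbances
0.5, second-order loadings ±0.5 with signs from correlations between
factor-block mean composites.

χ² = (N−1)·F_min, with the p-value from the central chi-square at the
conventionally counted df. The standardized solution rescales loadings to
unit factor and indicator variances and is made unique by two deterministic
orientation rules: each first-order factor is oriented so its anchor
indicator (the first listed) has the declared sign — negative for HDL
within dyslipidemia and for reciprocal-transformed IL-6 within inflammation,
so the factors read as "dyslipidemia risk" and "inflammation" — and each
second-order factor column is oriented so its largest-magnitude loading is
positive, which leaves the vagal-tone loading negative (higher load, lower
vagal tone) whenever the data say so.

## Fit indices and nested tests

* RMSEA = sqrt(max(χ² − df, 0) / (df (N − 1))). Both the N and N−1
  conventions round identically at two decimals for every case of interest;
  N−1 is fixed for determinism.
* CFI = 1 − max(χ²_M − df_M, 0)/max(χ²_B − df_B, χ²_M − df_M, 0), with the
  independence baseline Σ_B = diag(S) (so F_B = −ln|R|, df_B = p(p−1)/2).
* The average absolute standardized residual averages
  |s_ij − σ_ij|/sqrt(s_ii s_jj) over all p(p+1)/2 unique elements including
  the diagonal (the EQS convention); an off-diagonal-only variant is
  available as an option.
* Nested comparisons report Δχ² = max(χ²_restricted − χ²_full, 0) against a
  central chi-square with Δdf; a difference below −1e-4 raises a diagnostic
  warning (optimizer noise should never exceed that). Human-readable tables
  round half-up to two decimals; machine outputs keep full precision.

## Preprocessing

Exclusions are applied in a fixed order — medication flags, then the
acute-inflammation thresholds (IL-6 > 10 pg/ml or CRP > 10 mg/L, strict
inequalities, evaluated on raw values), then completeness of the
metabolic-syndrome components — and every excluded participant is tallied
once, at the first rule violated. Transforms: natural log for CRP, insulin,
glucose, triglycerides and all four HRV columns; reciprocal for IL-6;
identity otherwise. Covariate adjustment residualizes each transformed
indicator on an intercept, age, and dummy-coded sex and race via OLS prior
to covariance computation (rather than modeling covariates inside the
structural model) — the only convention consistent with the conventional
df arithmetic above, since residualized covariates contribute no moments or
parameters. Covariances use the unbiased N−1 denominator after listwise
deletion on each model's own variable set, which is how the unpaced variant
automatically analyzes a smaller N.

## Synthetic cohorts

The generator emulates a mid-life community cohort. Latent structure is
specified on the standardized *transformed* scale (the scale the CFA
analyzes): a single second-order allostatic-load factor with standardized
loadings 0.7 on the four metabolic system factors, 0.6 on inflammation and
−0.35 on vagal tone; indicator loadings 0.8 except glucose (0.35, a
deliberately weak marker of insulin resistance), with HDL (−0.8) and
transformed IL-6 (−0.8) running against their factors. The vagal factor is
indicated by both the paced and unpaced recordings so one cohort serves both
analysis variants. Disturbances and uniquenesses complete every variance to
1, so the population covariance is exactly the implied Σ of the generating
spec. A two-second-order-factor preset (`two_factor_population`) separates
an allostatic-load factor (metabolic 0.25, inflammation 0.75, vagal −0.55)
from a metabolic-syndrome factor (0.70 on the four metabolic systems);
these separations were calibrated by pilot computation of the population
noncentrality so the one- vs two-factor comparison has high power at
n = 645 while all disturbances stay well positive.

Covariate effects (age/sex/race, standardized coefficients of 0.10–0.25,
e.g. age on adiposity and blood pressure, sex on HDL, race on blood
pressure and CRP) are added with the structural part shrunk by
sqrt(1 − R²), so each transformed variable keeps unit variance and the
residual correlation structure after adjustment equals the population Σ
exactly. Variables are then mapped to raw units by inverting the analysis
transforms: log-scale variables are exponentiated with a lognormal moment
match to the raw mean/SD targets (a plausible mid-life profile: e.g. BMI
27.16 ± 5.38 kg/m², glucose 95.81 ± 16.68 mg/dl), identity variables are
affinely rescaled, and IL-6 is the reciprocal of a Gaussian N(0.7, 0.175²)
truncated at 0.05. That IL-6 choice is synthetic by necessity: a raw tail
as heavy as published descriptive statistics for IL-6 cannot coexist with a
genuinely Gaussian reciprocal scale bounded away from zero, and the
Gaussianity of the analyzed scale was judged more important than raw-tail
fidelity. Age is uniform on 30–54 years; sex 52% female; race 18%
African-American; smoking 15.8%.

Exclusion-rule violations are planted in exact counts: disjoint random
subsets get an IL-6 or CRP value above 10, a missing waist circumference, a
medication flag, or missing unpaced recordings; chance threshold crossers
among the remaining rows are redrawn just below the cutoff so the planted
counts are exact. This trims the IL-6/CRP right tails slightly;
`PopulationSpec.expected_marginals()` returns the moments a generated
cohort actually shows (computed by Gauss-Hermite quadrature), and the
marginal-fidelity tests check against those. The `study` preset generates
723 participants with 73 biomarker violators and 5 missing-component
participants (645 retained) and 20 retained participants missing unpaced
recordings (N = 625 for unpaced models).

What passing tests on these cohorts do *not* show about real data: latents
and errors are exactly Gaussian on the transformed scale, assay error,
floor/ceiling effects, non-linear covariate effects and missingness that is
informative rather than planted are all absent, and the paced/unpaced
recordings share a single latent rather than a method factor. Recovery
results here are a best case for the estimator, not a robustness claim.

## Statistical caveats found and handled

Two properties of this model family emerged during validation and are
deliberately reflected in the tests:

1. **Reported df vs sampling df.** Under the free-loading identification,
   each first-order block carries a scale trade-off (multiply the block's
   loadings by c, adjust the factor variance by 1/c²) that leaves Σ
   unchanged, so the implied-covariance manifold has dimension 2p + E (E =
   second-order edges), one less per first-order factor than the naive free
   parameter count. The minimized χ² is therefore asymptotically
   chi-square with df = p(p+1)/2 − 2p − E — for the single-factor
   allostatic-load model, 48 rather than the conventionally reported 42.
   Simulation confirms this exactly (exceed-95 rate 0.050 and KS p ≈ 0.36
   against χ²(48) at n = 645; the engine's minima match an independently
   parameterized reference fit to ~1e-9, ruling out under-minimization).
   The package reports the conventional df (as published analyses of this
   family do) for χ² p-values, RMSEA and CFI, and exposes
   `effective_degrees_of_freedom()` for calibration work; all
   simulation-calibration tests use the effective reference.

2. **The added-factor Δχ² null is singular.** Testing the one- against the
   two-second-order-factor model puts all four added loadings at zero under
   the null, where Σ depends on them only quadratically (first derivatives
   vanish). The null Δχ²(4) is consequently stochastically somewhat larger
   than a central χ²(4) (empirical mean ≈ 4.8, rejection rate ≈ 7–9% at
   the nominal 5% level across 500 replicates). The tests assert the
   rejection-rate band rather than distributional equality, and users
   should treat borderline Δχ² p-values for this particular comparison
   with corresponding caution.

## Problem sizes used in the test suite and acceptance script

Null calibration: 500 pipeline replicates at n = 645 (shared across tests).
Loading-recovery bias: 100 replicates at n = 5000. Oracle equivalence: 20
sample-covariance fixtures at n = 645 (10 eight-variable, 10
twelve-variable models) against the marker-identified, numeric-gradient
reference implementation. Pipeline-closure checks use n ∈ {645, 2000,
10000}. These sizes give Monte-Carlo error comfortably inside every
asserted tolerance while keeping the whole suite around a minute.

## Known limitations

No standard errors or robust (Satorra-Bentler) corrections; no mean
structures, categorical estimators or multiple-group models; missing data
handled by listwise deletion only. Unstandardized loadings are reported
under the free-loading convention and are unique only up to the per-block
scale trade-off described above (Σ, χ², all fit indices and the
standardized solution are unaffected). The two-factor model's MS-specific
loadings are weakly determined when the factors are strongly interrelated;
treat individual path coefficients from `model3_two_factor` with caution
even when the overall comparison favors it.
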