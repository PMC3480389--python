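"""Preprocessing: exclusion cascade, transforms, covariate adjustment,
covariance bridge, RMSSD, descriptives, CSV round-trip."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as sts

from alcfa import (
    ExclusionCriteria,
    adjust_covariates,
    apply_exclusions,
    descriptives,
    read_cohort,
    rmssd,
    sample_covariance,
    transform_variables,
    write_cohort,
)
from alcfa.cohort import (
    CohortConfigError,
    CohortDataError,
    MEDICATION_FLAGS,
    METABOLIC_INDICATORS,
)
from alcfa.simulate import ExclusionPlants, PopulationSpec, generate_cohort


def plant_cohort(n=100, n_il6=10, n_missing=5, seed=0):
    """Cohort with exactly the requested rule violations planted."""
    pop = PopulationSpec(
        plants=ExclusionPlants(n_biomarker=n_il6, n_missing_ms=n_missing), seed=seed
    )
    return generate_cohort(pop, n)


class TestApplyExclusions:
    def test_planted_violations_are_removed_exactly(self):
        cohort = plant_cohort(100, n_il6=10, n_missing=5)
        kept, tally = apply_exclusions(cohort)
        assert len(kept) == 85
        assert tally["il6_crp"] == 10
        assert tally["incomplete"] == 5

    def test_empty_cohort_passes_through(self):
        cohort = plant_cohort(5, 0, 0).iloc[0:0]
        kept, tally = apply_exclusions(cohort)
        assert len(kept) == 0
        assert all(v == 0 for v in tally.values())

    def test_idempotent(self):
        cohort = plant_cohort(100, 10, 5)
        once, _ = apply_exclusions(cohort)
        twice, tally2 = apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)
        assert sum(tally2.values()) == 0

    def test_tally_accounts_for_every_removal(self):
        cohort = plant_cohort(200, 17, 9, seed=3)
        cohort.loc[cohort.index[:4], "med_antihypertensive"] = True
        kept, tally = apply_exclusions(cohort)
        assert sum(tally.values()) == len(cohort) - len(kept)

    def test_medications_counted_before_biomarkers(self):
        """A participant violating both rules is tallied at the first."""
        cohort = plant_cohort(50, 5, 0)
        viol = cohort.index[cohort["il6"] > 10][0]
        cohort.loc[viol, "med_cold"] = True
        _, tally = apply_exclusions(cohort)
        assert tally["med_cold"] == 1
        assert tally["il6_crp"] == 4

    def test_threshold_is_strict(self):
        cohort = plant_cohort(20, 0, 0)
        cohort.loc[cohort.index[0], "il6"] = 10.0  # exactly at the limit
        cohort.loc[cohort.index[1], "crp"] = 10.0
        kept, _ = apply_exclusions(cohort)
        assert len(kept) == 20

    def test_unknown_flag_is_config_error(self):
        cohort = plant_cohort(10, 0, 0)
        crit = ExclusionCriteria(medication_flags_to_exclude=("med_nonexistent",))
        with pytest.raises(CohortConfigError):
            apply_exclusions(cohort, crit)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(CohortConfigError):
            ExclusionCriteria(il6_max=0.0)


class TestTransformVariables:
    def test_reciprocal_log_identity(self, tiny_cohort):
        out = transform_variables(tiny_cohort)
        assert out["il6"].iloc[0] == pytest.approx(0.5)          # 1/2.0
        assert out["glucose"].iloc[0] == pytest.approx(np.log(95.81))
        assert out["sbp"].iloc[0] == pytest.approx(116.35)       # identity

    def test_missing_stays_missing(self, tiny_cohort):
        tiny_cohort.loc[tiny_cohort.index[2], "crp"] = np.nan
        out = transform_variables(tiny_cohort)
        assert np.isnan(out["crp"].iloc[2])

    def test_nonpositive_value_names_participant_and_variable(self, tiny_cohort):
        tiny_cohort.loc[tiny_cohort.index[3], "il6"] = -1.0
        with pytest.raises(CohortDataError, match="il6"):
            transform_variables(tiny_cohort)

    def test_unknown_transform_rejected(self, tiny_cohort):
        with pytest.raises(CohortConfigError):
            transform_variables(tiny_cohort, {"il6": "sqrt"})


class TestAdjustCovariates:
    def test_empty_covariate_list_centers(self, tiny_cohort):
        out = adjust_covariates(tiny_cohort, [], variables=("sbp", "glucose"))
        assert out["sbp"].mean() == pytest.approx(0.0, abs=1e-8)
        assert out["glucose"].mean() == pytest.approx(0.0, abs=1e-8)

    def test_perfectly_explained_variable_vanishes(self, tiny_cohort):
        tiny_cohort["sbp"] = 2.0 * tiny_cohort["age"]
        out = adjust_covariates(tiny_cohort, ["age"], variables=("sbp",))
        assert np.allclose(out["sbp"], 0.0, atol=1e-8)

    def test_residuals_have_mean_zero(self, tiny_cohort):
        out = adjust_covariates(
            tiny_cohort, ["age", "sex", "race"], variables=("sbp", "glucose")
        )
        for col in ("sbp", "glucose"):
            assert out[col].mean() == pytest.approx(0.0, abs=1e-8)

    def test_planted_age_effect_leaves_noise_variance(self):
        """Residual variance after adjustment equals the planted noise
        variance, up to sampling error at n = 5000."""
        rng = np.random.default_rng(17)
        n = 5000
        age = rng.uniform(30, 54, n)
        noise = rng.normal(0, 1.0, n)
        df = pd.DataFrame({"sbp": 0.5 * age + noise, "age": age})
        out = adjust_covariates(df, ["age"], variables=("sbp",))
        assert out["sbp"].var(ddof=1) == pytest.approx(1.0, rel=0.06)

    def test_rank_deficient_design_rejected(self, tiny_cohort):
        tiny_cohort["age2"] = tiny_cohort["age"]
        with pytest.raises(CohortDataError, match="rank"):
            adjust_covariates(tiny_cohort, ["age", "age2"], variables=("sbp",))

    def test_missing_covariate_value_rejected(self, tiny_cohort):
        tiny_cohort.loc[tiny_cohort.index[0], "age"] = np.nan
        with pytest.raises(CohortDataError):
            adjust_covariates(tiny_cohort, ["age"], variables=("sbp",))

    def test_orthogonal_variable_covariance_unchanged(self):
        """Adjustment leaves variables already orthogonal to the covariates
        (population-orthogonal by construction) essentially untouched."""
        rng = np.random.default_rng(2)
        n = 400
        age = rng.uniform(30, 54, n)
        age_c = age - age.mean()
        y1, y2 = rng.normal(size=(2, n))
        # project out the covariate exactly, then compare covariances
        for y in (y1, y2):
            y -= age_c * (y @ age_c) / (age_c @ age_c)
        df = pd.DataFrame({"sbp": y1, "dbp": y2, "age": age})
        out = adjust_covariates(df, ["age"], variables=("sbp", "dbp"))
        before = np.cov(y1, y2)
        after = np.cov(out["sbp"], out["dbp"])
        assert np.allclose(before, after, atol=1e-8)


class TestSampleCovariance:
    def test_matches_hand_calculation_on_four_rows(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 1.0, 4.0, 3.0], "c": [1.0, 1.0, 2.0, 2.0]}
        )
        cov = sample_covariance(df, ["a", "b", "c"])
        # hand: mean a=2.5, b=2.5, c=1.5; e.g. cov(a,b) = (1.5+1.5+0.5+1.5... )
        expected = np.cov(df[["a", "b", "c"]].to_numpy(), rowvar=False, ddof=1)
        assert np.allclose(cov.S, expected)
        assert cov.N == 4

    def test_perfect_correlation_off_diagonal(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        df["b"] = 3.0 * df["a"]
        cov = sample_covariance(df, ["a", "b"])
        assert cov.S[0, 1] == pytest.approx(np.sqrt(cov.S[0, 0] * cov.S[1, 1]))

    def test_listwise_deletion_reduces_n(self):
        pop = PopulationSpec(plants=ExclusionPlants(n_missing_unpaced=20))
        cohort = generate_cohort(pop, 300, seed=1)
        paced = sample_covariance(cohort, ["hf_hrv_paced", "rmssd_paced", "sbp"])
        unpaced = sample_covariance(cohort, ["hf_hrv_unpaced", "rmssd_unpaced", "sbp"])
        assert paced.N == 300
        assert unpaced.N == 280

    def test_too_few_rows_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [2.0, 1.0], "c": [0.5, 0.7]})
        with pytest.raises(CohortDataError):
            sample_covariance(df, ["a", "b", "c"])

    @pytest.mark.parametrize("seed", range(3))
    def test_output_positive_semi_definite(self, seed):
        cohort = generate_cohort(PopulationSpec(), 60, seed=seed)
        cov = sample_covariance(cohort, ["sbp", "dbp", "bmi", "waist", "il6"])
        assert np.all(np.linalg.eigvalsh(cov.S) > -1e-10)
        assert np.allclose(cov.S, cov.S.T)


class TestRmssd:
    def test_constant_series_is_zero(self):
        assert rmssd([800.0, 800.0, 800.0]) == 0.0

    def test_hand_value(self):
        # sqrt((10^2 + 20^2)/2) = sqrt(250)
        assert rmssd([800.0, 810.0, 790.0]) == pytest.approx(15.8114, abs=1e-4)

    @given(
        shift=sts.floats(min_value=0.0, max_value=500.0),
        scale=sts.floats(min_value=0.1, max_value=10.0),
    )
    @settings(deadline=None, max_examples=25)
    def test_shift_invariant_and_scale_linear(self, shift, scale):
        base = np.array([800.0, 812.0, 795.0, 805.0, 790.0])
        r = rmssd(base)
        assert rmssd(base + shift) == pytest.approx(r, rel=1e-9)
        assert rmssd(base * scale) == pytest.approx(r * scale, rel=1e-9)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            rmssd([800.0])


class TestDescriptives:
    def test_constant_column_has_zero_sd(self, tiny_cohort):
        tiny_cohort["const"] = 5.0
        table = descriptives(tiny_cohort)
        sd = table.query("variable == 'const' and statistic == 'sd'")["value"].iloc[0]
        assert sd == 0.0

    def test_category_percentages_pass_through(self, tiny_cohort):
        table = descriptives(tiny_cohort)
        pct = table.query("variable == 'sex' and statistic == 'percent_female'")
        assert pct["value"].iloc[0] == pytest.approx(50.0)

    def test_empty_cohort_rejected(self, tiny_cohort):
        with pytest.raises(CohortDataError):
            descriptives(tiny_cohort.iloc[0:0])

    def test_generated_marginals_near_targets(self):
        """Sampling check: generated BMI matches its mean/SD target within
        three standard errors at the study's sample size."""
        pop = PopulationSpec()
        cohort = generate_cohort(pop, 645, seed=0)
        mean, sd = pop.marginal_targets["bmi"]
        se_mean = sd / np.sqrt(645)
        assert cohort["bmi"].mean() == pytest.approx(mean, abs=3 * se_mean)
        assert cohort["bmi"].std(ddof=1) == pytest.approx(sd, abs=3 * sd / np.sqrt(2 * 645))


class TestCsvRoundTrip:
    def test_missing_values_survive(self, tmp_path, tiny_cohort):
        tiny_cohort.loc[tiny_cohort.index[1], "crp"] = np.nan
        for flag in MEDICATION_FLAGS:
            tiny_cohort[flag] = False
        path = tmp_path / "cohort.csv"
        write_cohort(tiny_cohort, path)
        back = read_cohort(path)
        assert np.isnan(back["crp"].iloc[1])
        assert back["glucose"].iloc[0] == pytest.approx(95.81)
        assert back["med_cold"].dtype == bool

    def test_na_token_is_missing(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("il6,crp,sbp\n1.5,NA,120\n2.0,1.1,\n")
        df = read_cohort(path)
        assert np.isnan(df["crp"].iloc[0])
        assert np.isnan(df["sbp"].iloc[1])
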