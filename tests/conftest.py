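import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from alcfa import (
    CovarianceInput,
    build_model,
    default_population,
    generate_cohort,
    population_covariance,
    recovery_experiment,
    study_population,
)


@pytest.fixture(scope="session")
def pop_default():
    return default_population(seed=0)


@pytest.fixture(scope="session")
def pop_cov(pop_default):
    """Exact population covariance of the default generating structure."""
    return population_covariance(pop_default)


@pytest.fixture(scope="session")
def study_cohort():
    """723-participant raw cohort emulating the study's filter cascade."""
    return generate_cohort(study_population(seed=0), 723, seed=0)


def sample_cov_fixture(spec, pop_cov, seed, n=645):
    """Sample covariance of n multivariate-normal draws from the population."""
    sub = pop_cov.subset(spec.indicators)
    L = np.linalg.cholesky(sub.S)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(sub.names))) @ L.T
    return CovarianceInput(S=np.cov(X, rowvar=False), N=n, names=sub.names)


@pytest.fixture(scope="session")
def null_calibration(pop_default):
    """One shared 500-replicate null simulation at n = 645: Model 2 truth,
    Model 2 and Model 3 both fitted; used for the chi-square difference
    calibration, its distributional shape, and the nested-ordering check."""
    return recovery_experiment(
        pop_default, 645, 500, seed=0, fit_name="model2_al",
        compare_full="model3_two_factor",
    )


@pytest.fixture
def tiny_cohort():
    """Hand-sized raw cohort with covariates and flags, no rule violations."""
    n = 8
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {
            "il6": [2.0, 1.5, 1.0, 2.5, 3.0, 1.2, 0.8, 2.2],
            "crp": [1.0, 2.0, 0.5, 3.0, 1.5, 2.5, 0.9, 1.1],
            "glucose": [95.81, 90.0, 100.0, 85.0, 110.0, 99.0, 92.0, 101.0],
            "insulin": [12.0, 10.0, 15.0, 9.0, 20.0, 11.0, 8.0, 13.0],
            "sbp": [116.35, 120.0, 110.0, 130.0, 125.0, 118.0, 109.0, 122.0],
            "waist": [35.0, 33.0, 38.0, 31.0, 40.0, 36.0, 30.0, 37.0],
            "age": [30.0, 35.0, 40.0, 45.0, 50.0, 38.0, 42.0, 47.0],
            "sex": ["male", "female"] * 4,
            "race": ["european_american"] * 6 + ["african_american"] * 2,
        }
    )
    df["bmi"] = rng.normal(27, 3, n)
    return df
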