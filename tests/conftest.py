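"""Shared fixtures: small synthetic cohorts and study-condition configs."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bimm import (
    GeneratorConfig,
    RFParams,
    calibrate_intercept,
    generate_cohort,
)

settings.register_profile("ci", max_examples=100, derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """200 persons, mixed signal, moderate clustering — fast unit-test table."""
    cfg = GeneratorConfig(
        n_persons=200,
        n_person_covariates=4,
        n_knee_covariates=2,
        effect_sizes=(0.6, -0.5, 0.4, -0.3, 0.5, -0.4),
        random_intercept_sd=1.5,
        intercept=-1.0,
        seed=1,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def fast_rf() -> RFParams:
    return RFParams(n_trees=60, min_samples_leaf=5)


def person_informative_config(
    n_persons: int, sigma_b: float, prevalence: float
) -> GeneratorConfig:
    """High within-person-correlation study fixture: all outcome signal is
    carried by 8 person-level covariates; 12 knee-level covariates are pure
    noise; sigma_b adds an unpredictable person effect on top."""
    cfg = GeneratorConfig(
        n_persons=n_persons,
        n_person_covariates=8,
        n_knee_covariates=12,
        effect_sizes=(1.2, -1.0, 0.9, -0.8, 0.7, -0.6, 0.5, -0.4) + (0.0,) * 12,
        random_intercept_sd=sigma_b,
        binary_fraction=0.25,
        seed=11,
    )
    return dataclasses.replace(cfg, intercept=calibrate_intercept(cfg, prevalence))


def simulate_mixed_model_data(
    n_persons: int, beta0: float, beta1: float, sigma_b: float, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (y, p, person_ids) directly from the random-intercept logistic
    model with p ~ Uniform — the generating process the fitter assumes."""
    from scipy.special import expit

    rng = np.random.default_rng(seed)
    pid = np.repeat(np.arange(n_persons), 2)
    p = rng.uniform(0.02, 0.98, 2 * n_persons)
    b = rng.normal(0.0, sigma_b, n_persons)[pid]
    y = (rng.random(2 * n_persons) < expit(beta0 + beta1 * p + b)).astype(int)
    return y, p, pid
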