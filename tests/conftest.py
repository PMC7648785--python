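import numpy as np
import pandas as pd
import pytest

from expomed.data import CohortTable
from expomed.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_draw():
    """One default-condition analytic subset (n = 161, p = 38, q = 61)."""
    return generate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def full_cohort_draw():
    """The same study conditions without case-control subsampling."""
    return generate_cohort(SimConfig(seed=11), full_cohort=True)


def single_pathway_config(seed: int, n: int = 1000, alpha: float = 1.0, beta: float = 1.0) -> SimConfig:
    """One exposure, one mediator, one active pathway with known effects."""
    return SimConfig(
        n_cohort=n,
        n_cases_sampled=1,
        n_controls_sampled=1,
        class_sizes={"phthalate": 1},
        group_sizes={"cox": 1},
        within_class_rho=0.0,
        within_group_rho=0.0,
        alpha_matrix=np.array([[alpha]]),
        beta_m=np.array([beta]),
        beta_a=np.array([0.0]),
        covariate_effects=0.2,
        seed=seed,
    )


def plain_cohort(y: np.ndarray, covariates: pd.DataFrame | None = None, weights=None) -> CohortTable:
    """Minimal cohort wrapper around a continuous outcome for unit tests."""
    n = len(y)
    if covariates is None:
        covariates = pd.DataFrame({"z": np.random.default_rng(2718).standard_normal(n)})
    cov = covariates
    return CohortTable(
        subject_id=np.arange(n),
        covariates=cov,
        outcome_continuous=np.asarray(y, float),
        outcome_binary=np.zeros(n, int),
        outcome_binary_spontaneous=np.zeros(n, int),
        case_status=np.array(["control"] * n),
        ipw_weight=np.ones(n) if weights is None else np.asarray(weights, float),
    )
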