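"""Shared fixtures: small synthetic datasets and reduced model scenarios."""

import numpy as np
import pytest

from rdsjoint.config import ModelConfig
from rdsjoint.likelihood import pack_dataset
from rdsjoint.model_core import (
    ExacerbationEpisode,
    ModelParameters,
    SubjectHistory,
    re_covariance_to_unconstrained,
)
from rdsjoint.simulate import (
    CovariateSpec,
    SimulationConfig,
    default_case_study_config,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def case_config():
    return default_case_study_config(n_subjects=150)


@pytest.fixture(scope="session")
def small_dataset(case_config):
    """150 subjects from the case-study-like scenario (fixed seed)."""
    subjects, truth = simulate_dataset(case_config, seed=101)
    return subjects, truth


@pytest.fixture(scope="session")
def small_packed(case_config, small_dataset):
    return pack_dataset(small_dataset[0], case_config.model)


def make_mini_config(n_subjects=300, seed=0, re_components="BW",
                     include_severity=False, include_zi=True,
                     family="lognormal"):
    """A reduced scenario (intercept + one binary covariate) for fast fits."""
    model = ModelConfig(
        rate_covariates=["treatment"],
        duration_covariates=["treatment"],
        severity_covariates=["treatment"],
        zi_covariates=[],
        family_rate=family,
        family_duration=family,
        include_severity=include_severity,
        re_components=re_components,
    )
    sds = {"B": 0.8, "W": 0.5, "S": 1.0}
    act = [c for c in "BWS" if c in re_components
           and (c != "S" or include_severity)
           and (c != "W" or True)]
    re_log_sd = np.zeros(3)
    for c in act:
        re_log_sd["BWS".index(c)] = np.log(sds[c])
    corr = np.zeros(3)
    if len(act) >= 2:
        _, corr = re_covariance_to_unconstrained(
            np.exp(re_log_sd), [0.4, 0.4, 0.4])
    params = ModelParameters(
        beta_B=[4.6, np.log(2.0)],
        beta_W=[2.4, -0.15],
        beta_S=[-1.6, 0.2],
        beta_ZI=[-0.8],
        shape_B=1.2,
        shape_W=0.62,
        re_log_sd=re_log_sd,
        re_corr_chol=corr,
    )
    return SimulationConfig(
        n_subjects=n_subjects,
        true_params=params,
        model=model,
        covariates=[CovariateSpec("treatment", "bernoulli", (0.5,))],
        follow_up=[(347.0, 0.55), (224.0, 0.45)],
        dropout_rate=4e-4,
        seed=seed,
    )


@pytest.fixture()
def toy_subject():
    """A hand-built two-episode subject."""
    return SubjectHistory(
        subject_id="toy",
        follow_up=200.0,
        episodes=[
            ExacerbationEpisode(onset_time=30.0, termination_time=40.0, severity=1),
            ExacerbationEpisode(onset_time=100.0, termination_time=112.0, severity=0),
        ],
        final_gap=88.0,
        final_gap_censored=1,
        covariates={"treatment": 1.0, "age_decades": 5.0, "female": 0.0},
    )
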