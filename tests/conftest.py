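import numpy as np
import pytest

from cogbeta.cohort import GeneratorConfig, TrueParams, generate_cohort
from cogbeta.mcmc import McmcConfig
from cogbeta.preprocess import ModelTerms, build_analysis_set, build_design

# generative truth shaped like the published final model; everything else zero
TRUE_BETAS = {
    "age": -0.110,
    "sex": 0.262,
    "edu": 0.062,
    "apoe2": 0.037,
    "apoe4": -0.382,
    "edu_x_apoe2": -0.063,
    "edu_x_apoe4": -0.082,
}


@pytest.fixture(scope="session")
def small_cohort():
    """240 participants, no missingness: quick fits, still hierarchical."""
    cfg = GeneratorConfig(
        n_participants=240, seed=11, true_params=TrueParams(betas=dict(TRUE_BETAS))
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_analysis_set(small_cohort):
    return build_analysis_set(small_cohort, "e2_vs_e3")


@pytest.fixture(scope="session")
def small_design(small_analysis_set):
    terms = ModelTerms({"age", "sex", "edu", "apoe", "edu_x_apoe"})
    return build_design(small_analysis_set, terms)


@pytest.fixture()
def quick_mcmc():
    """Short chains for unit tests (defaults stay at 8000/4000)."""
    return McmcConfig(n_chains=2, n_adapt_burnin=600, n_iter=600, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
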