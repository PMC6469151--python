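import numpy as np
import pytest

from minpglm import Dataset, FamilyLink, ScenarioSpec, binomial_intercept
from minpglm import generate_dataset


@pytest.fixture(scope="session")
def fl_gauss():
    return FamilyLink.from_names("gaussian", "identity")


@pytest.fixture(scope="session")
def fl_logit():
    return FamilyLink.from_names("binomial", "logit")


@pytest.fixture(scope="session")
def fl_probit():
    return FamilyLink.from_names("binomial", "probit")


@pytest.fixture(scope="session")
def fl_poisson():
    return FamilyLink.from_names("poisson", "log")


@pytest.fixture(scope="session")
def logit_null_ds():
    """Null binomial-logit dataset: n=300, one adjustment covariate,
    marginal prevalence ~0.3, X lognormal and independent of Y given Z."""
    g0 = binomial_intercept(0.3, [0.3])
    return generate_dataset(ScenarioSpec(n=300, gamma=(g0, 0.3), seed=20250301))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
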