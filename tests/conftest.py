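import numpy as np
import pytest

import graphppl as gp
from graphppl.distributions import Normal


@pytest.fixture(scope="session")
def regression_data():
    return gp.regression_fixture()


@pytest.fixture(scope="session")
def regression_model(regression_data):
    x, y = regression_data
    return gp.build_regression_model(x, y)


@pytest.fixture(scope="session")
def coal_model():
    return gp.build_coal_model()


def make_conjugate_model(y):
    """Normal(0,1) prior on theta, unit-variance Normal likelihood."""
    m = gp.ProbModel()
    th = m.add_free("theta", Normal(0, 1))
    m.add_observed("y", Normal(mu=th, sigma=1), np.atleast_1d(y))
    return m


def conjugate_posterior(y):
    """Exact posterior mean and sd for make_conjugate_model."""
    y = np.atleast_1d(y)
    n = y.size
    return y.sum() / (n + 1), np.sqrt(1.0 / (n + 1))


def conjugate_log_evidence(y):
    """Exact marginal likelihood: y ~ N(0, I + 11^T)."""
    from scipy.stats import multivariate_normal
    y = np.atleast_1d(y)
    n = y.size
    return float(multivariate_normal(np.zeros(n),
                                     np.eye(n) + np.ones((n, n))).logpdf(y))


@pytest.fixture()
def conjugate_y():
    return np.random.default_rng(5).normal(2.0, 1.0, size=5)
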