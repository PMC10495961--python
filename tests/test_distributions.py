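"""Log-densities, log-CDFs, seeded draws and wrappers for every family."""

import math

import numpy as np
import pytest
from scipy import stats

import graphppl as gp
from graphppl import tensor as pt
from graphppl.distributions import (
    Normal, HalfNormal, Exponential, Uniform, LogNormal, Gamma, Dirichlet,
    Bernoulli, Binomial, Poisson, DiscreteUniform, Multinomial,
    DirichletMultinomial, Censored, Truncated, draw, set_strict,
    ParameterError, UnsupportedOperationError, default_initial_value,
)


def lp(dist, value):
    return float(dist.logp(pt.constant(value)).eval({}))


def lp_vec(dist, values):
    return np.asarray(dist.logp(pt.constant(np.asarray(values))).eval({}))


def lc(dist, value):
    return float(dist.logcdf(pt.constant(value)).eval({}))


def test_closed_form_log_densities():
    assert lp(Normal(0, 1), 0.0) == pytest.approx(-0.9189385, abs=1e-6)
    assert lp(Poisson(1), 0) == pytest.approx(-1.0)
    assert lp(Exponential(1), 1.0) == pytest.approx(-1.0)
    assert lp(Uniform(0, 2), 1.0) == pytest.approx(-math.log(2))
    assert lp(Bernoulli(p=0.25), 1) == pytest.approx(math.log(0.25))
    assert lp(DiscreteUniform(1851, 1961), 1900) == pytest.approx(-math.log(111))


SCALAR_FAMILIES = [
    (Normal(0.5, 1.3), stats.norm(0.5, 1.3)),
    (HalfNormal(2.0), stats.halfnorm(0, 2.0)),
    (Exponential(1.7), stats.expon(0, 1 / 1.7)),
    (Uniform(2, 3), stats.uniform(2, 1)),
    (LogNormal(0.5, 0.8), stats.lognorm(0.8, 0, np.exp(0.5))),
    (Gamma(2.0, 3.0), stats.gamma(2.0, 0, 1 / 3.0)),
    (Bernoulli(p=0.3), stats.bernoulli(0.3)),
    (Binomial(10, 0.4), stats.binom(10, 0.4)),
    (Poisson(3.5), stats.poisson(3.5)),
    (DiscreteUniform(2, 9), stats.randint(2, 10)),
]


@pytest.mark.parametrize("dist,ref", SCALAR_FAMILIES,
                         ids=[d.family for d, _ in SCALAR_FAMILIES])
def test_logp_matches_reference_distribution(dist, ref):
    if dist.support.continuous:
        xs = ref.ppf(np.linspace(0.01, 0.99, 11))
        want = ref.logpdf(xs)
    else:
        xs = np.arange(ref.ppf(0.01), ref.ppf(0.999) + 1)
        want = ref.logpmf(xs)
    got = np.array([lp(dist, x) for x in xs])
    np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-12)


@pytest.mark.parametrize("dist,ref", SCALAR_FAMILIES,
                         ids=[d.family for d, _ in SCALAR_FAMILIES])
def test_normalization_and_out_of_support(dist, ref):
    s = dist.support
    if dist.support.continuous:
        lo = s.lower if np.isfinite(s.lower) else ref.ppf(1e-12)
        hi = s.upper if np.isfinite(s.upper) else ref.ppf(1 - 1e-12)
        xs = np.linspace(lo + 1e-9, hi - 1e-9, 20001)
        total = np.trapezoid(np.exp(lp_vec(dist, xs)), xs)
    else:
        xs = np.arange(max(s.lower, 0), ref.ppf(1 - 1e-12) + 1)
        total = np.sum(np.exp(lp_vec(dist, xs)))
    assert total == pytest.approx(1.0, abs=1e-3)
    if np.isfinite(s.lower):
        assert lp(dist, s.lower - 1.0) == -np.inf


def test_logcdf_closed_forms_and_monotonicity():
    assert lc(Normal(0, 1), 0.0) == pytest.approx(math.log(0.5))
    assert lc(Uniform(0, 1), 0.25) == pytest.approx(math.log(0.25))
    assert lc(Uniform(0, 1), 2.0) == 0.0
    for dist, ref in [(Normal(0, 1), stats.norm()),
                      (Exponential(2.0), stats.expon(0, 0.5)),
                      (LogNormal(0, 1), stats.lognorm(1)),
                      (Poisson(4.0), stats.poisson(4.0)),
                      (Uniform(0, 1), stats.uniform())]:
        xs = np.linspace(ref.ppf(0.02), ref.ppf(0.98), 20)
        got = np.array([lc(dist, x) for x in xs])
        np.testing.assert_allclose(got, ref.logcdf(xs), rtol=1e-7, atol=1e-9)
        assert np.all(np.diff(got) >= -1e-12)


def test_exponential_logcdf_vs_quadrature():
    dist = Exponential(2.0)
    for x in np.linspace(0.05, 3.0, 20):
        grid = np.linspace(1e-9, x, 4001)
        dens = np.exp(lp_vec(dist, grid))
        assert lc(dist, x) == pytest.approx(np.log(np.trapezoid(dens, grid)),
                                            abs=1e-4)


def test_dirichlet_multinomial_logp_matches_independent_oracle():
    dist = DirichletMultinomial(n=6, a=np.array([1.0, 1.0, 1.0]))
    val = np.array([2.0, 2.0, 2.0])
    got = lp(dist, val)
    want = stats.dirichlet_multinomial(np.ones(3), 6).logpmf([2, 2, 2])
    assert got == pytest.approx(float(want), rel=1e-10)
    # and sums to 1 over the whole support
    total = 0.0
    for i in range(7):
        for j in range(7 - i):
            total += math.exp(lp(dist, np.array([i, j, 6 - i - j],
                                                dtype=float)))
    assert total == pytest.approx(1.0, abs=1e-10)


def test_multivariate_logp_values():
    d = Dirichlet(np.array([2.0, 3.0, 4.0]))
    x = np.array([0.2, 0.3, 0.5])
    assert lp(d, x) == pytest.approx(stats.dirichlet(np.array([2., 3., 4.])
                                                     ).logpdf(x), rel=1e-10)
    m = Multinomial(10, np.array([0.2, 0.3, 0.5]))
    v = np.array([2.0, 3.0, 5.0])
    assert lp(m, v) == pytest.approx(
        stats.multinomial(10, [0.2, 0.3, 0.5]).logpmf([2, 3, 5]), rel=1e-10)


@pytest.mark.parametrize("dist,ref", [(d, r) for d, r in SCALAR_FAMILIES
                                      if d.support.continuous],
                         ids=[d.family for d, _ in SCALAR_FAMILIES
                              if d.support.continuous])
def test_draws_pass_ks_against_cdf(dist, ref):
    rv = dist.rv("x")
    samples = draw(rv, draws=5000, seed=1234).ravel()
    d_stat = stats.kstest(samples, ref.cdf).statistic
    crit_001 = 1.949 / math.sqrt(len(samples))  # 0.1% KS critical value
    assert d_stat < crit_001


def test_draw_seeding_and_bounds():
    u = Uniform(0, 1).rv("u")
    a = draw(u, draws=100, seed=7)
    b = draw(u, draws=100, seed=7)
    assert np.array_equal(a, b)
    assert np.all((a >= 0) & (a <= 1))
    n = Normal(0, 1).rv("n")
    x = draw(n, draws=1000, seed=3)
    assert abs(x.mean()) < 4 / math.sqrt(1000)
    assert abs(x.std() - 1) < 0.15


def test_draw_through_graph_mirrors_ancestral_structure():
    a = Uniform(0, 1).rv("a")
    b = Normal(mu=a, sigma=1).rv("b")
    x = b + pt.constant(np.array([2.0, 3.0, 4.0]))
    d = draw(x, draws=1000, seed=11)
    assert d.shape == (1000, 3)
    np.testing.assert_allclose(d.mean(axis=0), [2.5, 3.5, 4.5], atol=0.15)


def test_distinct_rv_nodes_get_independent_streams():
    x = Normal(0, 1).rv("x")
    y = Normal(0, 1).rv("y")
    d = draw(x - y, draws=2000, seed=5)
    assert d.std() == pytest.approx(math.sqrt(2), abs=0.1)


def test_default_initial_values():
    assert default_initial_value(Normal(0, 1)) == 0.0
    assert default_initial_value(DiscreteUniform(1851, 1961)) == 1906.0
    assert lp(DiscreteUniform(1851, 1961), 1906.0) > -np.inf
    np.testing.assert_allclose(default_initial_value(Dirichlet(np.ones(4))),
                               np.full(4, 0.25))


def test_censored_normal_upper_bound():
    c = Censored(Normal(0, 1), upper=0.0)
    assert lp(c, 0.0) == pytest.approx(math.log(0.5))
    assert lp(c, 1.0) == -np.inf
    assert lp(c, -1.0) == pytest.approx(lp(Normal(0, 1), -1.0))


def test_censored_total_probability_is_one():
    c = Censored(Exponential(1.0), lower=0.5, upper=2.0)
    atom_lo = math.exp(lp(c, 0.5))
    atom_hi = math.exp(lp(c, 2.0))
    grid = np.linspace(0.5 + 1e-9, 2.0 - 1e-9, 20001)
    interior = np.trapezoid(np.exp(lp_vec(c, grid)), grid)
    assert atom_lo + atom_hi + interior == pytest.approx(1.0, abs=1e-3)


def test_truncated_renormalizes_and_rejects_outside():
    t = Truncated(Normal(0, 1), lower=-1.0, upper=2.0)
    grid = np.linspace(-1 + 1e-9, 2 - 1e-9, 20001)
    total = np.trapezoid(np.exp(lp_vec(t, grid)), grid)
    assert total == pytest.approx(1.0, abs=1e-3)
    assert lp(t, -1.5) == -np.inf
    s = t.sample(np.random.default_rng(0), 200, {"mu": 0.0, "sigma": 1.0})
    assert np.all((s >= -1) & (s <= 2))


def test_censored_requires_logcdf_for_finite_bounds():
    with pytest.raises(UnsupportedOperationError):
        Censored(Gamma(2.0, 1.0), upper=1.0)  # Gamma logcdf not implemented


def test_overdispersion_of_dirichlet_multinomial():
    # matched mean: DM(n, a) with a = c * p has mean n*p like Multinomial(n, p)
    p = np.array([0.3, 0.3, 0.4])
    n, conc = 50, 5.0
    rng_seed = 21
    dm = draw(DirichletMultinomial(n=n, a=conc * p).rv("dm"),
              draws=4000, seed=rng_seed)
    mn = draw(Multinomial(n=n, p=p).rv("mn"), draws=4000, seed=rng_seed)
    assert np.all(dm.var(axis=0) > mn.var(axis=0))
    np.testing.assert_allclose(dm.mean(axis=0), mn.mean(axis=0), rtol=0.1)


def test_strict_mode_parameter_validation():
    with pytest.raises(ParameterError):
        Normal(0, -1).sample(np.random.default_rng(0), None,
                             {"mu": 0.0, "sigma": -1.0})
    # the symbolic log-density path propagates NaN rather than raising
    assert np.isnan(lp(Normal(0, -1), 0.5))
    set_strict(False)
    try:
        assert np.isnan(lp(Exponential(-2.0), 1.0) * 0 + lp(Normal(0, -1), 0.5))
    finally:
        set_strict(True)


def test_bernoulli_requires_exactly_one_parameterization():
    with pytest.raises(ParameterError):
        Bernoulli(p=0.5, logit_p=0.0)
    with pytest.raises(ParameterError):
        Bernoulli()
    assert lp(Bernoulli(logit_p=0.0), 1) == pytest.approx(math.log(0.5))
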