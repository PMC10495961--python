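"""MCMC kernels: leapfrog, NUTS, Metropolis and compound assignment."""

import math

import numpy as np
import pytest
from scipy import stats

import graphppl as gp
from graphppl.distributions import (
    Normal, Exponential, Poisson, DiscreteUniform, HalfNormal,
)
from graphppl.model import ProbModel
from graphppl.step_methods import (
    NUTS, Metropolis, CompoundStep, assign_steps, leapfrog, adapt_mass_diag,
    DualAveraging,
)


# ---------------------------------------------------------------------------
# leapfrog
# ---------------------------------------------------------------------------


def test_leapfrog_is_time_reversible():
    rng = np.random.default_rng(0)
    grad = lambda q: -q  # standard normal target
    mass = np.array([1.0, 2.0])
    for _ in range(10):
        q0, p0 = rng.normal(size=2), rng.normal(size=2)
        q1, p1 = leapfrog(q0, p0, 0.3, grad, mass)
        q2, p2 = leapfrog(q1, -p1, 0.3, grad, mass)
        np.testing.assert_allclose(q2, q0, atol=1e-10)
        np.testing.assert_allclose(-p2, p0, atol=1e-10)


def test_leapfrog_energy_drift_is_small():
    grad = lambda q: -q
    mass = np.ones(1)
    q, p = np.array([1.0]), np.array([0.5])

    def hamiltonian(q, p):
        return 0.5 * q @ q + 0.5 * p @ p

    h0 = hamiltonian(q, p)
    for _ in range(100):
        q, p = leapfrog(q, p, 0.1, grad, mass)
    assert abs(hamiltonian(q, p) - h0) < 0.01


def test_leapfrog_zero_momentum_zero_gradient_is_identity():
    q, p = leapfrog(np.array([2.0]), np.array([0.0]), 0.5,
                    lambda q: np.zeros_like(q), np.ones(1))
    assert q[0] == 2.0 and p[0] == 0.0


def test_leapfrog_flags_nonfinite_gradient():
    with pytest.raises(FloatingPointError):
        leapfrog(np.array([1.0]), np.array([1.0]), 0.1,
                 lambda q: np.array([np.nan]), np.ones(1))


# ---------------------------------------------------------------------------
# adaptation pieces
# ---------------------------------------------------------------------------


def test_dual_averaging_moves_stepsize_in_right_direction():
    # the log(10*eps0) anchor biases the very first iterate upward by
    # design; monotonicity holds from the second update on
    up = DualAveraging(0.5, target=0.8)
    ups = [up.update(1.0) for _ in range(20)]
    assert all(b >= a for a, b in zip(ups[1:], ups[2:]))
    assert ups[-1] > 0.5
    down = DualAveraging(0.5, target=0.8)
    downs = [down.update(0.0) for _ in range(20)]
    assert all(b <= a for a, b in zip(downs[1:], downs[2:]))
    assert downs[-1] < 0.5


def test_adapt_mass_diag_recovers_scale_ratio():
    rng = np.random.default_rng(1)
    draws = rng.normal(0, [1.0, 10.0], size=(500, 2))
    mass = adapt_mass_diag(draws)
    ratio = mass[1] / mass[0]
    assert 50 < ratio < 200  # within 2x of the true 100
    assert np.all(mass > 0)


def test_adapt_mass_diag_constant_draws_stays_positive():
    mass = adapt_mass_diag(np.ones((50, 3)))
    assert np.all(mass > 0)


def test_adapt_mass_diag_single_coordinate():
    mass = adapt_mass_diag(np.random.default_rng(0).normal(size=(100, 1)))
    assert mass.shape == (1,) and mass[0] > 0


# ---------------------------------------------------------------------------
# NUTS on known targets
# ---------------------------------------------------------------------------


def _sample_names(trace, name):
    return trace.posterior[name].values


def test_nuts_acceptance_approaches_target_on_standard_normal():
    m = ProbModel()
    m.add_free("x", Normal(0, 1), shape=10)
    tr = gp.sample(m, draws=500, tune=500, chains=2, seed=8)
    acc = tr.sample_stats["mean_tree_accept"].values.mean()
    assert 0.7 < acc < 0.92


def test_nuts_recovers_correlated_normal_moments():
    # x ~ N(0,1), y | x ~ N(rho x, 1 - rho^2): joint is a correlated normal
    rho = 0.9
    m = ProbModel()
    x = m.add_free("x", Normal(0, 1))
    m.add_free("y", Normal(mu=rho * x, sigma=math.sqrt(1 - rho ** 2)))
    tr = gp.sample(m, draws=1000, tune=1000, chains=4, seed=10)
    for name in ("x", "y"):
        s = _sample_names(tr, name)
        e = gp.ess(s, "bulk")
        mcse = s.std() / math.sqrt(e)
        assert abs(s.mean()) < 3 * mcse + 1e-9
        assert abs(s.var() - 1.0) < 0.1
    xy = (_sample_names(tr, "x") * _sample_names(tr, "y")).mean()
    assert xy == pytest.approx(rho, abs=0.1)


def test_nuts_flags_divergences_on_funnel_geometry():
    # Neal-style funnel: v ~ N(0, 3^2), x | v ~ N(0, exp(v))
    m = ProbModel()
    v = m.add_free("v", Normal(0, 3))
    m.add_free("x", Normal(mu=0.0, sigma=gp.tensor.exp(v / 2.0)), shape=4)
    tr = gp.sample(m, draws=500, tune=500, chains=2, seed=2)
    assert tr.sample_stats["diverging"].values.sum() > 0


def test_seeded_chains_are_bitwise_reproducible():
    def run():
        m = gp.build_regression_model()
        return gp.sample(m, draws=50, tune=50, chains=2, seed=33)
    a, b = run(), run()
    assert np.array_equal(a.posterior["b"].values, b.posterior["b"].values)
    assert np.array_equal(a.posterior["a"].values, b.posterior["a"].values)


def test_nuts_max_depth_one_is_single_accept_reject_step():
    m = ProbModel()
    m.add_free("x", Normal(0, 1))
    step = NUTS(var_names=["x"], max_treedepth=1, step_size=0.5)
    point = {"x": 0.3}
    rng = np.random.default_rng(0)
    step.bind(m, point, rng, n_tune=0)
    _, stats = step.step(point, tuning=False)
    assert stats["tree_depth"] <= 1 + 1
    assert stats["n_steps"] <= 2


# ---------------------------------------------------------------------------
# Metropolis
# ---------------------------------------------------------------------------


def test_metropolis_matches_discrete_uniform_occupancy():
    m = ProbModel()
    m.add_free("k", DiscreteUniform(0, 10))
    tr = gp.sample(m, draws=12500, tune=500, chains=4, seed=3)
    k = tr.posterior["k"].values.ravel().astype(int)
    counts = np.bincount(k, minlength=11)
    # chi-square against the uniform pmf at alpha=0.001
    chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
    # wide threshold: the chain is autocorrelated, compare per-ESS counts
    e = gp.ess(tr.posterior["k"].values, "bulk")
    scale = len(k) / e
    assert chi2 / scale < stats.chi2(10).ppf(0.999)
    assert set(np.unique(k)) <= set(range(11))


def test_metropolis_zero_scale_never_moves():
    m = ProbModel()
    m.add_free("x", Normal(0, 1))
    step = Metropolis(var_names=["x"], scale=1e-12)
    point = {"x": 0.5}
    step.bind(m, point, np.random.default_rng(0), n_tune=0)
    step.integer = True  # rounded proposals collapse to zero increments
    for _ in range(20):
        point, _ = step.step(point, tuning=False)
    assert point["x"] == 0.5


def test_metropolis_config_validates_scale():
    with pytest.raises(ValueError):
        Metropolis(scale=0.0)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------


def test_assignment_on_coal_model(coal_model):
    compound = assign_steps(coal_model)
    kinds = [(type(s).__name__, tuple(s.var_names)) for s in compound.steps]
    assert ("NUTS", ("t_0_log__", "t_1_log__")) in kinds
    assert ("Metropolis", ("sp",)) in kinds
    assert ("Metropolis", ("acc_missing",)) in kinds


def test_assignment_all_continuous_is_single_nuts(regression_model):
    compound = assign_steps(regression_model)
    assert len(compound.steps) == 1
    assert isinstance(compound.steps[0], NUTS)
    assert "NUTS: [a, b]" in compound.description


def test_assignment_all_discrete_is_metropolis_only():
    m = ProbModel()
    m.add_free("k", DiscreteUniform(0, 5))
    m.add_free("j", Poisson(2.0))
    compound = assign_steps(m)
    assert all(isinstance(s, Metropolis) for s in compound.steps)


def test_assignment_empty_model_raises():
    with pytest.raises(ValueError):
        assign_steps(ProbModel())


def test_detailed_balance_continuous_metropolis():
    """Long-run occupancy of Metropolis on a half-normal matches the target."""
    m = ProbModel()
    m.add_free("h", HalfNormal(1))
    step = Metropolis(var_names=["h_log__"])
    tr = gp.sample(m, draws=10000, tune=1000, chains=2, seed=9,
                   step=CompoundStep([step]))
    h = tr.posterior["h"].values.ravel()
    e = gp.ess(tr.posterior["h"].values, "bulk")
    thinned = h[:: max(1, int(len(h) / e))]
    d = stats.kstest(thinned, stats.halfnorm(0, 1).cdf).statistic
    assert d < 1.949 / math.sqrt(len(thinned))  # KS at alpha=0.001
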