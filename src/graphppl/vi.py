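"""Mean-field automatic-differentiation variational inference (ADVI).

The implementation follows the operator view of variational inference: an
objective is an operator applied to an approximation family, averaged under
the approximation, and passed through a distance function.  For the KL
operator the test function drops out (the operator is constant over test
functions), the distance is the identity, and the objective reduces to

    E_q[ log q(z) - log p(z, x) ]

i.e. the negative ELBO up to the constant log evidence.  The shipped family
is the mean-field normal over the transformed model space, with the scale
parameterized through a softplus so optimization is unconstrained, and the
gradient estimated by the location-scale reparameterization
``z = mu + softplus(rho) * eps``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import ProbModel
from .trace import TraceStore, dataset_from_arrays

__all__ = ["MeanField", "Objective", "build_objective", "fit_advi",
           "approx_sample"]


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    from scipy.special import expit
    return expit(x)


class MeanField:
    """Independent normal approximation over transformed free coordinates."""

    def __init__(self, model: ProbModel, mu=None, rho=None):
        if model.discrete_vars:
            raise TypeError("mean-field ADVI needs continuous variables only")
        point = model.initial_point(jitter=False)
        self.names = [fv.transformed for fv in model.free.values()]
        self.shapes = [np.shape(point[n]) for n in self.names]
        self.sizes = [int(np.prod(s)) if s else 1 for s in self.shapes]
        self.dim = sum(self.sizes)
        start = np.concatenate([np.ravel(np.asarray(point[n], dtype=float))
                                for n in self.names])
        self.mu = np.array(mu, dtype=float) if mu is not None else start
        # softplus(rho) ~ 0.1 initially: small but nonzero exploration
        self.rho = np.array(rho, dtype=float) if rho is not None \
            else np.full(self.dim, math.log(math.expm1(0.1)))

    @property
    def sigma(self) -> np.ndarray:
        return _softplus(self.rho)

    def unravel(self, vec: np.ndarray) -> dict:
        out, i = {}, 0
        for n, sh, sz in zip(self.names, self.shapes, self.sizes):
            out[n] = vec[i:i + sz].reshape(sh) if sh else float(vec[i])
            i += sz
        return out

    def sample_unconstrained(self, draws: int, rng: np.random.Generator):
        eps = rng.normal(size=(draws, self.dim))
        return self.mu + self.sigma * eps, eps

    def logq(self, z: np.ndarray) -> np.ndarray:
        s = self.sigma
        return np.sum(-0.5 * ((z - self.mu) / s) ** 2 - np.log(s)
                      - 0.5 * math.log(2 * math.pi), axis=-1)


@dataclass
class Objective:
    """Operator / distance / test-function triple; KL + identity shipped."""

    operator: str = "KL"
    distance: str = "identity"
    test_function: object = None

    def __post_init__(self):
        if self.operator != "KL" or self.distance != "identity":
            raise NotImplementedError(
                "only the KL operator with identity distance is implemented")


def build_objective(model: ProbModel, approx: MeanField,
                    objective: Objective | None = None):
    """Monte-Carlo estimator of E_q[log q(z) - log p(z, x)].

    Returns a callable ``estimate(mc_draws, seed) -> float``.  The KL
    operator yields the same function for every test function, so
    ``objective.test_function`` is accepted and ignored.
    """
    objective = objective or Objective()
    lg = model.compile_logp_grad(jacobian=True)

    def estimate(mc_draws: int = 100, seed=None) -> float:
        rng = np.random.default_rng(seed)
        z, _ = approx.sample_unconstrained(mc_draws, rng)
        logps = np.array([lg(approx.unravel(z[i]))[0]
                          for i in range(mc_draws)], dtype=float)
        return float(np.mean(approx.logq(z) - logps))

    return estimate


def fit_advi(model: ProbModel, n_steps: int = 20000, lr: float = 1e-2,
             mc_draws: int = 1, seed=None, beta1: float = 0.9,
             beta2: float = 0.999, eps_adam: float = 1e-8,
             average_tail: float = 0.25):
    """Stochastic gradient descent (Adam) on the mean-field KL objective.

    Returns ``(approx, objective_trace)`` where the trace records the
    per-step stochastic objective estimates (for convergence plotting).
    The returned parameters are Polyak-averaged over the last
    ``average_tail`` fraction of iterations, which removes most of the
    stationary stochastic-gradient jitter.
    """
    approx = MeanField(model)
    lg = model.compile_logp_grad(jacobian=True)
    rng = np.random.default_rng(seed)
    m_mu = np.zeros(approx.dim)
    v_mu = np.zeros(approx.dim)
    m_rho = np.zeros(approx.dim)
    v_rho = np.zeros(approx.dim)
    history = np.empty(n_steps)
    names = approx.names
    avg_start = int(n_steps * (1.0 - average_tail)) if lr > 0 else n_steps
    avg_mu = np.zeros(approx.dim)
    avg_rho = np.zeros(approx.dim)
    n_avg = 0
    for t in range(1, n_steps + 1):
        sigma = approx.sigma
        eps = rng.normal(size=(mc_draws, approx.dim))
        g_mu = np.zeros(approx.dim)
        g_sigma = np.zeros(approx.dim)
        obj = 0.0
        for k in range(mc_draws):
            z = approx.mu + sigma * eps[k]
            lp, gdict = lg(approx.unravel(z))
            if not np.isfinite(lp):
                raise FloatingPointError(
                    f"ADVI objective became non-finite at step {t}")
            grad_z = np.concatenate([np.ravel(np.asarray(gdict[n], dtype=float))
                                     for n in names])
            g_mu += -grad_z
            g_sigma += -grad_z * eps[k]
            obj += -lp
        g_mu /= mc_draws
        g_sigma /= mc_draws
        # entropy part: d/dsigma E[log q] = -1/sigma (no MC noise)
        g_sigma += -1.0 / sigma
        g_rho = g_sigma * _sigmoid(approx.rho)
        obj = obj / mc_draws + float(np.sum(
            -0.5 * eps[-1] ** 2 - np.log(sigma) - 0.5 * math.log(2 * math.pi)))
        history[t - 1] = obj
        if not np.all(np.isfinite(g_mu)) or not np.all(np.isfinite(g_rho)):
            raise FloatingPointError(
                f"ADVI gradient became non-finite at step {t}")
        for g, m_, v_, param in ((g_mu, m_mu, v_mu, approx.mu),
                                 (g_rho, m_rho, v_rho, approx.rho)):
            m_ *= beta1
            m_ += (1 - beta1) * g
            v_ *= beta2
            v_ += (1 - beta2) * g * g
            mhat = m_ / (1 - beta1 ** t)
            vhat = v_ / (1 - beta2 ** t)
            param -= lr * mhat / (np.sqrt(vhat) + eps_adam)
        if t > avg_start:
            avg_mu += approx.mu
            avg_rho += approx.rho
            n_avg += 1
    if n_avg:
        approx.mu = avg_mu / n_avg
        approx.rho = avg_rho / n_avg
    return approx, history


def approx_sample(approx: MeanField, model: ProbModel, draws: int = 1000,
                  seed=None) -> TraceStore:
    """Draws from the fitted approximation, back-transformed, as a trace."""
    rng = np.random.default_rng(seed)
    z, _ = approx.sample_unconstrained(draws, rng)
    posterior = {}
    dims = {}
    for fv in model.free.values():
        i = approx.names.index(fv.transformed)
        j = sum(approx.sizes[:i])
        u = z[:, j:j + approx.sizes[i]]
        shape = approx.shapes[i]
        u = u.reshape((draws,) + tuple(shape)) if shape else u[:, 0]
        x = u if fv.transform is None else fv.transform.backward_array(u)
        posterior[fv.name] = x[None]
        dims[fv.name] = fv.dims
    ds = dataset_from_arrays(posterior, dims, model.coords)
    return TraceStore({"posterior": ds},
                      metadata={"method": "advi", "seed": seed})
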