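"""Likelihood-tempered sequential Monte Carlo, marginal likelihood and ABC.

The sampler bridges from the prior to the posterior through a tempered
sequence ``prior * likelihood^beta`` with ``beta`` raised adaptively so the
relative effective sample size of the incremental weights stays near a
target (0.5 by default).  Each stage reweights, resamples systematically and
mutates the particles with a few Metropolis-Hastings passes whose proposal
covariance is estimated from the current ensemble (scaled by 2.38^2 / d), or
with an independent MH kernel using an ensemble-moment normal proposal.  The
log marginal likelihood accumulates as the sum of stage log-mean incremental
weights.

In ABC mode an explicit likelihood is replaced by the Gaussian
pseudo-likelihood ``exp(-distance^2 / (2 eps^2))`` of simulator output
against the observed data.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import xarray as xr

from . import tensor as pt
from .model import ProbModel, _eval_with_rvs
from .trace import TraceStore, dataset_from_arrays

__all__ = ["smc_sample", "abc_smc", "SimulatorSpec", "adapt_beta",
           "resample_systematic", "ParticleEnsemble"]

logger = logging.getLogger("graphppl")


@dataclass
class SimulatorSpec:
    """Forward simulator + distance + kernel bandwidth for ABC.

    ``simulate(params: dict, rng) -> pseudo-data``;
    ``distance(pseudo_data, data) -> float >= 0``.
    """

    simulate: Callable
    distance: Callable
    epsilon: float = 1.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


class ParticleEnsemble:
    """Positions (transformed space), log-weights and tempering state."""

    def __init__(self, positions: np.ndarray, names, shapes):
        self.positions = np.asarray(positions, dtype=float)  # (N, d)
        self.n, self.d = self.positions.shape
        self.names = list(names)
        self.shapes = list(shapes)
        self.log_weights = np.full(self.n, -math.log(self.n))
        self.beta = 0.0
        self.stage = 0
        self.log_ml = 0.0

    def point(self, i: int) -> dict:
        out, j = {}, 0
        for name, shape in zip(self.names, self.shapes):
            size = int(np.prod(shape)) if shape else 1
            chunk = self.positions[i, j:j + size]
            out[name] = chunk.reshape(shape) if shape else float(chunk[0])
            j += size
        return out


def ess_of_logweights(logw: np.ndarray) -> float:
    logw = logw - logw.max()
    w = np.exp(logw)
    w = w / w.sum()
    return 1.0 / np.sum(w * w)


def adapt_beta(beta: float, loglikes: np.ndarray, n: int,
               ess_target: float = 0.5, tol: float = 1e-10,
               max_iter: int = 50) -> float:
    """Largest beta' <= 1 with relative incremental-weight ESS near target."""
    target = ess_target * n
    if ess_of_logweights((1.0 - beta) * loglikes) >= target:
        return 1.0
    lo, hi = beta, 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if ess_of_logweights((mid - beta) * loglikes) > target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return max(0.5 * (lo + hi), beta + tol)


def resample_systematic(weights: np.ndarray, rng: np.random.Generator
                        ) -> np.ndarray:
    """Systematic resampling; offspring counts are unbiased (N * w_i)."""
    n = len(weights)
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions)


def _split_logp(model: ProbModel):
    """Compiled prior (incl. Jacobian) and likelihood parts of the joint."""
    terms = model.logp_terms(jacobian=True)
    prior_terms = [terms[fv.name] for fv in model.free.values()
                   if fv.own_prior_term]
    like_terms = [terms[ov.name] for ov in model.observed.values()]
    # missing-variable priors live inside the observed full-vector term
    inputs = list(model.value_inputs().values())

    def total(ts):
        if not ts:
            return pt.constant(0.0)
        s = ts[0]
        for t in ts[1:]:
            s = s + t
        return s

    return (pt.compile_fn(inputs, [total(prior_terms)]),
            pt.compile_fn(inputs, [total(like_terms)]))


def _prior_particles(model: ProbModel, n: int, rng_seed) -> ParticleEnsemble:
    from .sampling import _make_rngs, _forward_draw
    rngs = _make_rngs(model, rng_seed)
    names = [fv.transformed for fv in model.free.values()]
    rows = []
    shapes = None
    for _ in range(n):
        free_d, _, _ = _forward_draw(model, rngs)
        row = []
        sh = []
        for fv in model.free.values():
            x = np.asarray(free_d[fv.name], dtype=float)
            u = x if fv.transform is None else fv.transform.forward_value(x)
            u = np.asarray(u, dtype=float)
            sh.append(u.shape)
            row.append(np.ravel(u))
        shapes = sh
        rows.append(np.concatenate(row) if row else np.empty(0))
    return ParticleEnsemble(np.asarray(rows), names, shapes)


def mutate(ensemble: ParticleEnsemble, target_logp, kernel: str,
           n_steps: int, rng: np.random.Generator,
           integer_mask: np.ndarray | None = None):
    """MH passes per particle targeting prior * likelihood^beta.

    ``MH``: random-walk with ensemble covariance scaled by 2.38^2 / d.
    ``IMH``: independent proposals from the ensemble-moment normal.
    Returns the acceptance rate.
    """
    if n_steps == 0:
        return 0.0
    pos = ensemble.positions
    n, d = pos.shape
    mean = pos.mean(axis=0)
    cov = np.cov(pos.T) if d > 1 else np.atleast_2d(np.var(pos))
    cov = np.atleast_2d(cov) + 1e-10 * np.eye(d)
    if kernel == "MH":
        chol = np.linalg.cholesky(cov * (2.38 ** 2 / d))
    elif kernel == "IMH":
        chol = np.linalg.cholesky(cov)
        inv = np.linalg.inv(cov)
        logdet = np.linalg.slogdet(cov)[1]

        def prop_logq(x):
            z = x - mean
            return -0.5 * (z @ inv @ z) - 0.5 * logdet
    else:
        raise ValueError("kernel must be 'MH' or 'IMH'")

    cur_logp = np.array([target_logp(ensemble.point(i)) for i in range(n)])
    accepted = 0
    total = 0
    for _ in range(n_steps):
        if kernel == "MH":
            prop = pos + rng.normal(size=(n, d)) @ chol.T
        else:
            prop = mean + rng.normal(size=(n, d)) @ chol.T
        if integer_mask is not None and integer_mask.any():
            prop[:, integer_mask] = np.round(prop[:, integer_mask])
        for i in range(n):
            p = prop[i]
            point = dict(zip(ensemble.names, _unflatten(p, ensemble.shapes)))
            lp = target_logp(point)
            log_ratio = lp - cur_logp[i]
            if kernel == "IMH":
                log_ratio += prop_logq(pos[i]) - prop_logq(p)
            total += 1
            if math.log(rng.random() + 1e-300) < log_ratio:
                pos[i] = p
                cur_logp[i] = lp
                accepted += 1
    return accepted / max(total, 1)


def _unflatten(vec, shapes):
    out, j = [], 0
    for shape in shapes:
        size = int(np.prod(shape)) if shape else 1
        chunk = vec[j:j + size]
        out.append(chunk.reshape(shape) if shape else float(chunk[0]))
        j += size
    return out


def smc_sample(model: ProbModel, draws: int = 2000, kernel: str = "MH",
               seed=None, n_steps: int = 5, ess_target: float = 0.5,
               pseudo_loglike=None):
    """Tempered SMC posterior sampling with marginal-likelihood estimate.

    Returns ``(trace, log_marginal_likelihood)``.  ``pseudo_loglike``, if
    given, replaces the observed-data likelihood (used by :func:`abc_smc`).
    """
    if draws < 50:
        raise ValueError("SMC needs at least 50 particles")
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_init, s_resample, s_mutate = root.spawn(3)
    rng_res = np.random.default_rng(s_resample)
    rng_mut = np.random.default_rng(s_mutate)

    prior_fn, like_fn = _split_logp(model)
    ens = _prior_particles(model, draws, s_init)
    integer_mask = _integer_mask(model, ens)

    if pseudo_loglike is None:
        def loglike(point):
            return float(like_fn(point))
    else:
        loglike = pseudo_loglike

    lls = np.array([loglike(ens.point(i)) for i in range(ens.n)])
    if not np.any(np.isfinite(lls)):
        raise RuntimeError("all prior particles have -inf likelihood; "
                           "check the model/data")
    betas = []
    accept_rates = []
    log_ml_increments = []
    while ens.beta < 1.0:
        beta_new = adapt_beta(ens.beta, lls, ens.n, ess_target=ess_target)
        delta = beta_new - ens.beta
        logw = delta * lls
        logw = np.where(np.isfinite(logw), logw, -np.inf)
        # evidence increment: log mean of incremental weights
        inc = float(np.logaddexp.reduce(logw) - math.log(ens.n))
        log_ml_increments.append(inc)
        ens.log_ml += inc
        w = np.exp(logw - logw.max())
        w = w / w.sum()
        idx = resample_systematic(w, rng_res)
        ens.positions = ens.positions[idx].copy()
        lls = lls[idx]
        ens.beta = beta_new
        ens.stage += 1
        betas.append(beta_new)

        beta_c = ens.beta

        def tempered(point):
            lp = float(prior_fn(point))
            if not np.isfinite(lp):
                return -np.inf
            ll = loglike(point)
            if not np.isfinite(ll):
                return -np.inf
            return lp + beta_c * ll

        acc = mutate(ens, tempered, kernel, n_steps, rng_mut,
                     integer_mask=integer_mask)
        accept_rates.append(acc)
        lls = np.array([loglike(ens.point(i)) for i in range(ens.n)])
        logger.info("SMC stage %d: beta=%.4f accept=%.2f", ens.stage,
                    ens.beta, acc)

    posterior = {}
    dims = {}
    for fv, shape in zip(model.free.values(), ens.shapes):
        j = sum(int(np.prod(s)) if s else 1
                for s in ens.shapes[: ens.names.index(fv.transformed)])
        size = int(np.prod(shape)) if shape else 1
        u = ens.positions[:, j:j + size]
        u = u.reshape((ens.n,) + tuple(shape)) if shape else u[:, 0]
        x = u if fv.transform is None else fv.transform.backward_array(u)
        posterior[fv.name] = x[None]  # single chain
        dims[fv.name] = fv.dims
    if model.deterministics:
        names = list(model.deterministics)
        vals = {k: [] for k in names}
        for i in range(ens.n):
            rv_values = {fv.rv.nid: posterior[fv.name][0, i]
                         for fv in model.free.values()}
            outs = _eval_with_rvs([model.deterministics[k] for k in names],
                                  rv_values)
            for k, o in zip(names, outs):
                vals[k].append(np.asarray(o))
        for k in names:
            posterior[k] = np.stack(vals[k])[None]
            dims[k] = model.det_dims.get(k)
    stage_stats = dataset_from_arrays(
        {"beta": np.asarray(betas)[None],
         "accept_rate": np.asarray(accept_rates)[None],
         "log_ml_increment": np.asarray(log_ml_increments)[None]},
        {}, {})
    trace = TraceStore({
        "posterior": dataset_from_arrays(posterior, dims, model.coords),
        "sample_stats": stage_stats,
    }, metadata={"log_marginal_likelihood": ens.log_ml, "kernel": kernel,
                 "stages": ens.stage, "particles": ens.n, "seed": seed})
    return trace, ens.log_ml


def _integer_mask(model: ProbModel, ens: ParticleEnsemble) -> np.ndarray:
    mask = np.zeros(ens.d, dtype=bool)
    j = 0
    for fv, shape in zip(model.free.values(), ens.shapes):
        size = int(np.prod(shape)) if shape else 1
        if not fv.rv.dist.support.continuous:
            mask[j:j + size] = True
        j += size
    return mask


def abc_smc(model: ProbModel, simulator: SimulatorSpec, observed,
            draws: int = 2000, kernel: str = "MH", seed=None,
            n_steps: int = 5):
    """SMC-ABC: Gaussian pseudo-likelihood in the simulator distance.

    The model supplies priors over the parameters; the likelihood is
    ``exp(-d(sim(params), observed)^2 / (2 eps^2))``.  A raising simulator
    assigns the particle a ``-inf`` pseudo-log-likelihood (counted and
    warned about).
    """
    root = np.random.SeedSequence(seed)
    s_sim, s_smc = root.spawn(2)
    sim_rng = np.random.default_rng(s_sim)
    failures = [0]

    constrainers = {
        fv.transformed: (fv.name, fv.transform)
        for fv in model.free.values()}

    def pseudo(point):
        params = {}
        for tname, (name, transform) in constrainers.items():
            u = np.asarray(point[tname], dtype=float)
            params[name] = u if transform is None \
                else transform.backward_array(u)
        try:
            sim = simulator.simulate(params, sim_rng)
            d = float(simulator.distance(sim, observed))
        except Exception:
            failures[0] += 1
            return -np.inf
        return -d * d / (2.0 * simulator.epsilon ** 2)

    trace, log_ml = smc_sample(model, draws=draws, kernel=kernel,
                               seed=s_smc, n_steps=n_steps,
                               pseudo_loglike=pseudo)
    if failures[0]:
        import warnings
        warnings.warn(f"ABC simulator raised {failures[0]} times; those "
                      "particles got -inf pseudo-likelihood")
    trace.metadata["abc_epsilon"] = simulator.epsilon
    trace.metadata["simulator_failures"] = failures[0]
    return trace
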