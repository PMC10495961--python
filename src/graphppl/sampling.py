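"""User-facing inference drivers.

``sample`` runs the compound MCMC kernel over several chains and packages
constrained-space draws, recomputed deterministics and per-draw sampler
statistics into a :class:`~graphppl.trace.TraceStore`.  Forward sampling
(``sample_prior_predictive``, ``sample_posterior_predictive``) reuses the
same model definition without user intervention; missing observed entries
are imputed by sampling the full observed vector forward.  ``find_MAP``
optimizes the joint log-density in transformed coordinates (without the
Jacobian correction, i.e. the mode of the constrained-space density) and
``compute_log_likelihood`` adds pointwise observed-data log-likelihoods.
"""

from __future__ import annotations

import copy
import logging
import time

import numpy as np
from scipy import optimize

from . import tensor as pt
from .model import ProbModel, _eval_with_rvs
from .step_methods import CompoundStep, assign_steps, NUTS
from .trace import TraceStore, dataset_from_arrays

__all__ = [
    "sample", "sample_prior_predictive", "sample_posterior_predictive",
    "find_MAP", "compute_log_likelihood",
]

logger = logging.getLogger("graphppl")

_MAX_INIT_TRIES = 100


def _constrained_point(model: ProbModel, point: dict) -> dict[str, np.ndarray]:
    out = {}
    for fv in model.free.values():
        u = np.asarray(point[fv.transformed], dtype=float)
        if fv.transform is None:
            out[fv.name] = u
        else:
            out[fv.name] = fv.transform.backward_array(u)
    return out


def _initial_points(model: ProbModel, chains: int, seed, jitter: bool):
    """Jittered, finite-density starting points (one per chain)."""
    clogp = model.compile_logp()
    root = np.random.SeedSequence(seed)
    chain_seeds = root.spawn(chains)
    points = []
    for c in range(chains):
        ss = chain_seeds[c]
        sub = ss.spawn(_MAX_INIT_TRIES)
        point = None
        for t in range(_MAX_INIT_TRIES):
            cand = model.initial_point(jitter=jitter, seed=sub[t])
            if np.isfinite(float(clogp(cand))):
                point = cand
                break
        if point is None:
            cand = model.initial_point(jitter=False)
            terms = model.logp_terms()
            sub_map = {fv.value_node.nid: cand[fv.transformed]
                       for fv in model.free.values()}
            bad = []
            for name, term in terms.items():
                val = pt.eval_node(term, {fv.value_node: cand[fv.transformed]
                                          for fv in model.free.values()})
                if not np.isfinite(val):
                    bad.append(name)
            raise RuntimeError(
                "could not find a finite starting density after "
                f"{_MAX_INIT_TRIES} jitter attempts; non-finite terms: {bad}")
        points.append(point)
    return points, chain_seeds


def sample(model: ProbModel, draws: int = 1000, tune: int = 1000,
           chains: int = 4, seed=None, step=None, target_accept: float = 0.8,
           discard_tuned_samples: bool = True) -> TraceStore:
    """Posterior sampling with automatic kernel assignment.

    Chains run sequentially with independent substreams derived from
    ``seed``; the output is bitwise reproducible per (seed, chain index).
    """
    if draws < 1 or tune < 0 or chains < 1:
        raise ValueError("need draws >= 1, tune >= 0, chains >= 1")
    if not model.free:
        raise ValueError("model has no free variables")
    t_start = time.time()
    points, chain_seeds = _initial_points(model, chains, seed, jitter=True)

    proto = step if step is not None else assign_steps(model)
    if isinstance(proto, CompoundStep):
        for s in proto.steps:
            if isinstance(s, NUTS):
                s.config.target_accept = target_accept
    logger.info("Compound step assignment: %s",
                getattr(proto, "description", proto))

    kept = draws if discard_tuned_samples else tune + draws
    chain_draws: list[dict[str, list]] = []
    chain_stats: list[dict[str, list]] = []
    for c in range(chains):
        stepper = copy.deepcopy(proto)
        rng = np.random.default_rng(chain_seeds[c].spawn(1)[0])
        point = points[c]
        stepper.bind(model, point, rng, tune)
        draws_c: dict[str, list] = {fv.transformed: []
                                    for fv in model.free.values()}
        stats_c: dict[str, list] = {}
        for i in range(tune + draws):
            tuning = i < tune
            point, stats = stepper.step(point, tuning)
            if tuning and discard_tuned_samples:
                continue
            for k, v in point.items():
                if k in draws_c:
                    draws_c[k].append(np.asarray(v))
            for k, v in stats.items():
                stats_c.setdefault(k, []).append(v)
        chain_draws.append(draws_c)
        chain_stats.append(stats_c)
        logger.info("chain %d done (%d + %d iterations)", c, tune, draws)

    # assemble posterior in constrained space
    posterior: dict[str, np.ndarray] = {}
    dims: dict[str, tuple] = {}
    for fv in model.free.values():
        stackd = np.stack([np.stack(cd[fv.transformed])
                           for cd in chain_draws])  # (chain, draw, ...)
        if fv.transform is not None:
            stackd = fv.transform.backward_array(stackd)
        posterior[fv.name] = stackd
        dims[fv.name] = fv.dims
    # deterministics recomputed per draw
    det_names = list(model.deterministics)
    if det_names:
        n_ch, n_dr = chains, kept
        det_vals = {k: [] for k in det_names}
        nodes = [model.deterministics[k] for k in det_names]
        for ci in range(n_ch):
            for di in range(n_dr):
                rv_values = {fv.rv.nid: posterior[fv.name][ci, di]
                             for fv in model.free.values()}
                outs = _eval_with_rvs(nodes, rv_values)
                for k, o in zip(det_names, outs):
                    det_vals[k].append(np.asarray(o))
        for k in det_names:
            arr = np.stack(det_vals[k]).reshape(
                (n_ch, n_dr) + np.shape(det_vals[k][0]))
            posterior[k] = arr
            dims[k] = model.det_dims.get(k)
    # combined observed/missing vectors as deterministic columns
    for ov in model.observed.values():
        if ov.mask.any() and ov.name not in posterior:
            mis = posterior[ov.missing_name]
            full = np.broadcast_to(
                np.where(ov.mask, 0.0, ov.data),
                mis.shape[:2] + ov.data.shape).copy()
            full[..., ov.mis_idx] = mis
            posterior[ov.name] = full
            dims[ov.name] = ov.dims

    stats_arrays = {}
    all_keys = sorted({k for sc in chain_stats for k in sc})
    for k in all_keys:
        stats_arrays[k] = np.stack([np.asarray(sc.get(k, [np.nan] * kept))
                                    for sc in chain_stats])

    groups = {
        "posterior": dataset_from_arrays(posterior, dims, model.coords),
        "sample_stats": dataset_from_arrays(stats_arrays, {}, {}),
    }
    obs_arrays = {ov.name: ov.data for ov in model.observed.values()}
    if obs_arrays:
        groups["observed_data"] = dataset_from_arrays(
            obs_arrays, {ov.name: ov.dims for ov in model.observed.values()},
            model.coords, leading=())
    meta = {"seed": seed, "tune": tune, "draws": draws, "chains": chains,
            "sampler": getattr(proto, "description", str(proto)),
            "runtime_s": time.time() - t_start}
    return TraceStore(groups, metadata=meta)


# ---------------------------------------------------------------------------
# Forward sampling
# ---------------------------------------------------------------------------


def _forward_draw(model: ProbModel, rngs: dict[str, np.random.Generator],
                  conditioned: dict[int, np.ndarray] | None = None):
    """One ancestral pass over free then observed variables.

    ``conditioned`` maps free-RV node ids to fixed values (posterior
    predictive); otherwise free variables are drawn from their priors.
    """
    values: dict[int, np.ndarray] = dict(conditioned or {})
    free_draws: dict[str, np.ndarray] = {}
    obs_draws: dict[str, np.ndarray] = {}
    for fv in model.free.values():
        if fv.rv.nid in values:
            free_draws[fv.name] = values[fv.rv.nid]
            continue
        dist = fv.rv.dist
        pnodes = [dist.params[k] for k in dist.param_names]
        pvals = dict(zip(dist.param_names, _eval_with_rvs(pnodes, values)))
        val = np.asarray(dist.sample(rngs[fv.name], fv.rv.size, pvals))
        values[fv.rv.nid] = val
        free_draws[fv.name] = val
    for ov in model.observed.values():
        dist = ov.rv.dist
        pnodes = [dist.params[k] for k in dist.param_names]
        pvals = dict(zip(dist.param_names, _eval_with_rvs(pnodes, values)))
        size = ov.data.shape[: ov.data.ndim - dist.support.event_rank] or None
        obs_draws[ov.name] = np.asarray(dist.sample(rngs[ov.name], size, pvals))
    det_vals = {}
    if model.deterministics:
        names = list(model.deterministics)
        outs = _eval_with_rvs([model.deterministics[k] for k in names], values)
        det_vals = dict(zip(names, outs))
    return free_draws, obs_draws, det_vals


def _make_rngs(model: ProbModel, seed) -> dict[str, np.random.Generator]:
    names = [fv.name for fv in model.free.values()] + list(model.observed)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    return {n: np.random.default_rng(s) for n, s in zip(names,
                                                        ss.spawn(len(names)))}


def sample_prior_predictive(model: ProbModel, samples: int = 500,
                            seed=None) -> TraceStore:
    """Forward draws of the priors and of observed variables ignoring data."""
    rngs = _make_rngs(model, seed)
    prior: dict[str, list] = {}
    prior_pred: dict[str, list] = {}
    for _ in range(int(samples)):
        free_d, obs_d, det_d = _forward_draw(model, rngs)
        for k, v in {**free_d, **det_d}.items():
            prior.setdefault(k, []).append(v)
        for k, v in obs_d.items():
            prior_pred.setdefault(k, []).append(v)
            ov = model.observed[k]
            if ov.mask.any():
                prior_pred.setdefault(f"{k}_observed", []).append(
                    v[ov.obs_idx])
    dims = {fv.name: fv.dims for fv in model.free.values()}
    dims.update({k: model.det_dims.get(k) for k in model.deterministics})
    obs_dims = {ov.name: ov.dims for ov in model.observed.values()}
    groups = {
        "prior": dataset_from_arrays(
            {k: np.asarray(v)[None] for k, v in prior.items()},
            dims, model.coords),
        "prior_predictive": dataset_from_arrays(
            {k: np.asarray(v)[None] for k, v in prior_pred.items()},
            obs_dims, model.coords),
    }
    return TraceStore(groups, metadata={"prior_samples": samples, "seed": seed})


def sample_posterior_predictive(model: ProbModel, trace: TraceStore,
                                seed=None) -> TraceStore:
    """Forward-sample observed variables conditional on each posterior draw."""
    if "posterior" not in trace.groups:
        raise ValueError("trace has no posterior group")
    post = trace.posterior
    for fv in model.free.values():
        if fv.name not in post:
            raise KeyError(f"posterior is missing variable {fv.name!r}")
    n_ch = post.sizes["chain"]
    n_dr = post.sizes["draw"]
    rngs = _make_rngs(model, seed)
    out: dict[str, list] = {}
    for ci in range(n_ch):
        for di in range(n_dr):
            conditioned = {
                fv.rv.nid: np.asarray(post[fv.name].values[ci, di])
                for fv in model.free.values()}
            _, obs_d, _ = _forward_draw(model, rngs, conditioned)
            for k, v in obs_d.items():
                out.setdefault(k, []).append(v)
    arrays = {}
    for k, v in out.items():
        arr = np.asarray(v)
        arrays[k] = arr.reshape((n_ch, n_dr) + arr.shape[1:])
    obs_dims = {ov.name: ov.dims for ov in model.observed.values()}
    ds = dataset_from_arrays(arrays, obs_dims, model.coords)
    return TraceStore({"posterior_predictive": ds},
                      metadata={"seed": seed})


# ---------------------------------------------------------------------------
# MAP and pointwise log-likelihood
# ---------------------------------------------------------------------------


def find_MAP(model: ProbModel, start: dict | None = None, maxeval: int = 10000,
             gtol: float = 1e-5, include_transformed: bool = False):
    """Maximum a posteriori point via quasi-Newton optimization.

    Optimizes the joint density in transformed coordinates *without* the
    Jacobian terms, i.e. the mode of the density over the constrained
    parameters, evaluated through the unconstraining reparameterization; the
    result is reported back-transformed (constrained).
    """
    if model.discrete_vars:
        names = [fv.name for fv in model.discrete_vars]
        raise TypeError(f"find_MAP needs continuous variables only; "
                        f"discrete: {names}")
    point = dict(model.initial_point(jitter=False))
    if start:
        point.update(start)
    for k, v in point.items():
        if not np.all(np.isfinite(np.asarray(v, dtype=float))):
            raise ValueError(f"non-finite start value for {k!r}")
    lg = model.compile_logp_grad(jacobian=False)
    names = [fv.transformed for fv in model.free.values()]
    shapes = [np.shape(point[n]) for n in names]
    sizes = [int(np.prod(s)) if s else 1 for s in shapes]

    def unravel(x):
        out, i = {}, 0
        for n, sh, sz in zip(names, shapes, sizes):
            out[n] = x[i:i + sz].reshape(sh) if sh else float(x[i])
            i += sz
        return out

    def neg(x):
        lp, g = lg(unravel(x))
        gv = np.concatenate([np.ravel(np.asarray(g[n], dtype=float))
                             for n in names])
        return -float(lp), -gv

    x0 = np.concatenate([np.ravel(np.asarray(point[n], dtype=float))
                         for n in names])
    res = optimize.minimize(neg, x0, jac=True, method="L-BFGS-B",
                            options={"maxfun": maxeval, "gtol": gtol,
                                     "ftol": 1e-14})
    sol = unravel(res.x)
    out = {}
    for fv in model.free.values():
        u = np.asarray(sol[fv.transformed], dtype=float)
        out[fv.name] = u if fv.transform is None \
            else fv.transform.backward_array(u)
        if include_transformed and fv.transform is not None:
            out[fv.transformed] = u
    return out


def compute_log_likelihood(model: ProbModel, trace: TraceStore) -> TraceStore:
    """Pointwise log-likelihood of the observed data at each posterior draw."""
    if "posterior" not in trace.groups:
        raise ValueError("trace has no posterior group")
    post = trace.posterior
    n_ch, n_dr = post.sizes["chain"], post.sizes["draw"]
    nodes = {}
    sub = model._rv_substitution()
    for ov in model.observed.values():
        value = model.observed_value_node(ov)
        elem = ov.rv.dist.logp(value)
        elem = pt.clone_replace([elem], sub)[0]
        nodes[ov.name] = elem
    out: dict[str, list] = {k: [] for k in nodes}
    names = list(nodes)
    node_list = [nodes[k] for k in names]
    for ci in range(n_ch):
        for di in range(n_dr):
            bindings = {}
            for fv in model.free.values():
                x = np.asarray(post[fv.name].values[ci, di], dtype=float)
                if fv.transform is None:
                    bindings[fv.value_node] = x
                else:
                    bindings[fv.value_node] = fv.transform.forward_value(x)
            vals = pt.eval_node(node_list, bindings)
            for k, v in zip(names, vals):
                ov = model.observed[k]
                v = np.asarray(v)
                if ov.mask.any():
                    v = v[ov.obs_idx]
                out[k].append(v)
    arrays = {}
    ll_dims = {}
    for k in names:
        arr = np.asarray(out[k])
        arrays[k] = arr.reshape((n_ch, n_dr) + arr.shape[1:])
        ov = model.observed[k]
        ll_dims[k] = None if ov.mask.any() else ov.dims
    ds = dataset_from_arrays(arrays, ll_dims, model.coords)
    trace.add_group("log_likelihood", ds)
    return trace
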