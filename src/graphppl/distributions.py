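"""Parametric distribution families over symbolic tensors.

Every family provides a closed-form log-density/mass built from graph
primitives (so it is differentiable by :func:`graphppl.tensor.grad`), seeded
forward draws through a ``numpy.random.Generator``, a default initial value
(means or medians, clipped into the support) and support metadata used to
pick the change-of-variable transform for gradient-based samplers.

Out-of-support values evaluate to ``-inf`` rather than raising: samplers
probe support boundaries routinely.  Invalid *parameters* (``sigma <= 0``,
``p`` outside [0, 1]) raise in strict mode (the default, toggled with
:func:`set_strict`) when hit on a numeric code path, and propagate NaN
otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import tensor as pt
from .tensor import TensorNode, as_tensor, constant, switch

__all__ = [
    "DistributionSpec", "RandomVariableNode", "Support", "set_strict",
    "Normal", "HalfNormal", "Exponential", "Uniform", "LogNormal", "Gamma",
    "Dirichlet", "Bernoulli", "Binomial", "Poisson", "DiscreteUniform",
    "Multinomial", "DirichletMultinomial", "Censored", "Truncated",
    "draw", "logp", "logcdf",
]

_STRICT = [True]


def set_strict(flag: bool) -> None:
    """Toggle strict parameter validation on numeric code paths."""
    _STRICT[0] = bool(flag)


class UnsupportedOperationError(NotImplementedError):
    pass


class ParameterError(ValueError):
    pass


def _check(cond: bool, msg: str, *arrays):
    if not cond:
        if _STRICT[0]:
            raise ParameterError(msg)
    return cond


NEG_INF = constant(-np.inf)
HALF_LOG_2_OVER_PI = 0.5 * (math.log(2.0) - math.log(math.pi))


@dataclass
class Support:
    """Support descriptor: continuity, bounds, simplex flag, event rank."""

    continuous: bool = True
    lower: float = -np.inf
    upper: float = np.inf
    simplex: bool = False
    event_rank: int = 0


def _log1mexp(logx: TensorNode) -> TensorNode:
    """log(1 - exp(logx)) for logx <= 0."""
    return pt.log(-pt.expm1(logx))


class DistributionSpec:
    """Base of all parametric families.

    Parameters are stored as tensor nodes (numbers are wrapped as
    constants), so families compose: a parameter may itself be a random
    variable or any expression over random variables.
    """

    family: str = "?"
    param_names: tuple[str, ...] = ()
    #: parameters whose trailing axis is the event axis (simplex weights etc.)
    event_params: tuple[str, ...] = ()

    def __init__(self, **params):
        if set(params) != set(self.param_names):
            raise ParameterError(
                f"{self.family} expects parameters {self.param_names}, "
                f"got {tuple(params)}")
        self.params: dict[str, TensorNode] = {
            k: as_tensor(v) for k, v in params.items()}

    # -- interface ----------------------------------------------------------
    @property
    def support(self) -> Support:  # pragma: no cover - overridden
        raise NotImplementedError

    def logp(self, value) -> TensorNode:
        raise NotImplementedError

    def logcdf(self, value) -> TensorNode:
        raise UnsupportedOperationError(
            f"{self.family} has no implemented logcdf")

    def sample(self, rng: np.random.Generator, size, pvals: dict):
        raise NotImplementedError

    def initial_value(self, pvals: dict):
        raise NotImplementedError

    def validate(self, pvals: dict) -> None:
        """Numeric parameter checks (strict mode raises)."""

    # -- plumbing -----------------------------------------------------------
    def param_rank(self) -> int:
        """Batch rank implied by the parameters alone."""
        r = 0
        for k, v in self.params.items():
            pr = v.rank if v.rank is not None else 0
            if k in self.event_params:
                pr -= 1
            r = max(r, pr)
        return r

    def rv(self, name=None, size=None) -> "RandomVariableNode":
        return RandomVariableNode(self, name=name, size=size)

    def _pshape(self, size, pvals):
        if size is None:
            shapes = []
            for k, v in pvals.items():
                s = np.shape(v)
                if k in self.event_params:
                    s = s[:-1]
                shapes.append(s)
            return np.broadcast_shapes(*shapes) if shapes else ()
        if np.isscalar(size):
            return (int(size),)
        return tuple(size)

    def __repr__(self):
        def fmt(v):
            if v.kind == "constant" and np.ndim(v.value) == 0:
                return f"{float(v.value):.2g}"
            if v.kind == "constant":
                return np.array2string(np.asarray(v.value), precision=2)
            return v.name or "<expr>"
        args = ", ".join(fmt(self.params[k]) for k in self.param_names)
        return f"{self.family}({args})"


class RandomVariableNode(TensorNode):
    """A distribution embedded in the tensor graph.

    Behaves as a TensorNode in expressions; parameter nodes are its graph
    operands so ancestral samplers and log-density assembly can traverse
    through it.
    """

    __slots__ = ("dist", "size")

    def __init__(self, dist: DistributionSpec, name=None, size=None):
        self.dist = dist
        self.size = (int(size),) if np.isscalar(size) else \
            (tuple(size) if size is not None else None)
        batch_rank = len(self.size) if self.size is not None else dist.param_rank()
        rank = batch_rank + dist.support.event_rank
        super().__init__("rv", inputs=[dist.params[k] for k in dist.param_names],
                         rank=rank, name=name)

    def __repr__(self):
        return f"{self.name or '<rv>'} ~ {self.dist!r}"


# ---------------------------------------------------------------------------
# Continuous scalar families
# ---------------------------------------------------------------------------


class Normal(DistributionSpec):
    family = "Normal"
    param_names = ("mu", "sigma")

    def __init__(self, mu=0.0, sigma=1.0):
        super().__init__(mu=mu, sigma=sigma)

    support = Support()

    def logp(self, value):
        v, mu, sigma = as_tensor(value), self.params["mu"], self.params["sigma"]
        z = (v - mu) / sigma
        return -0.5 * z * z - pt.log(sigma) - constant(0.5 * pt.LOG_2PI)

    def logcdf(self, value):
        v, mu, sigma = as_tensor(value), self.params["mu"], self.params["sigma"]
        return pt.log_ndtr((v - mu) / sigma)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        return rng.normal(pvals["mu"], pvals["sigma"],
                          size=self._pshape(size, pvals))

    def initial_value(self, pvals):
        return np.broadcast_to(np.asarray(pvals["mu"], dtype=float),
                               self._pshape(None, pvals)).copy()

    def validate(self, pvals):
        _check(np.all(np.asarray(pvals["sigma"]) > 0), "Normal: sigma must be > 0")


class HalfNormal(DistributionSpec):
    family = "HalfNormal"
    param_names = ("sigma",)

    def __init__(self, sigma=1.0):
        super().__init__(sigma=sigma)

    support = Support(lower=0.0)

    def logp(self, value):
        v, sigma = as_tensor(value), self.params["sigma"]
        inside = constant(HALF_LOG_2_OVER_PI) - pt.log(sigma) \
            - 0.5 * (v / sigma) ** 2
        return switch(v >= 0, inside, NEG_INF)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        return np.abs(rng.normal(0.0, pvals["sigma"],
                                 size=self._pshape(size, pvals)))

    def initial_value(self, pvals):
        s = np.asarray(pvals["sigma"], dtype=float)
        return np.broadcast_to(s * math.sqrt(2.0 / math.pi),
                               self._pshape(None, pvals)).copy()

    def validate(self, pvals):
        _check(np.all(np.asarray(pvals["sigma"]) > 0), "HalfNormal: sigma must be > 0")


class Exponential(DistributionSpec):
    family = "Exponential"
    param_names = ("lam",)

    def __init__(self, lam=1.0):
        super().__init__(lam=lam)

    support = Support(lower=0.0)

    def logp(self, value):
        v, lam = as_tensor(value), self.params["lam"]
        return switch(v >= 0, pt.log(lam) - lam * v, NEG_INF)

    def logcdf(self, value):
        v, lam = as_tensor(value), self.params["lam"]
        return switch(v > 0, _log1mexp(-lam * v), NEG_INF)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        return rng.exponential(1.0 / np.asarray(pvals["lam"], dtype=float),
                               size=self._pshape(size, pvals))

    def initial_value(self, pvals):
        return np.broadcast_to(1.0 / np.asarray(pvals["lam"], dtype=float),
                               self._pshape(None, pvals)).copy()

    def validate(self, pvals):
        _check(np.all(np.asarray(pvals["lam"]) > 0), "Exponential: lam must be > 0")


class Uniform(DistributionSpec):
    family = "Uniform"
    param_names = ("lower", "upper")

    def __init__(self, lower=0.0, upper=1.0):
        super().__init__(lower=lower, upper=upper)

    @property
    def support(self):
        return Support(lower=self._const("lower"), upper=self._const("upper"))

    def _const(self, key):
        node = self.params[key]
        if node.kind == "constant":
            return float(np.asarray(node.value))
        return -np.inf if key == "lower" else np.inf

    def logp(self, value):
        v = as_tensor(value)
        l, u = self.params["lower"], self.params["upper"]
        inside = (v >= l) * (v <= u)
        return switch(inside, -pt.log(u - l), NEG_INF)

    def logcdf(self, value):
        v = as_tensor(value)
        l, u = self.params["lower"], self.params["upper"]
        mid = pt.log((v - l) / (u - l))
        return switch(v < l, NEG_INF, switch(v > u, constant(0.0), mid))

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        return rng.uniform(pvals["lower"], pvals["upper"],
                           size=self._pshape(size, pvals))

    def initial_value(self, pvals):
        l = np.asarray(pvals["lower"], dtype=float)
        u = np.asarray(pvals["upper"], dtype=float)
        return np.broadcast_to((l + u) / 2.0, self._pshape(None, pvals)).copy()

    def validate(self, pvals):
        _check(np.all(np.asarray(pvals["lower"]) < np.asarray(pvals["upper"])),
               "Uniform: lower must be < upper")


class LogNormal(DistributionSpec):
    family = "LogNormal"
    param_names = ("mu", "sigma")

    def __init__(self, mu=0.0, sigma=1.0):
        super().__init__(mu=mu, sigma=sigma)

    support = Support(lower=0.0)

    def logp(self, value):
        v, mu, sigma = as_tensor(value), self.params["mu"], self.params["sigma"]
        z = (pt.log(v) - mu) / sigma
        inside = -0.5 * z * z - pt.log(sigma) - pt.log(v) \
            - constant(0.5 * pt.LOG_2PI)
        return switch(v > 0, inside, NEG_INF)

    def logcdf(self, value):
        v, mu, sigma = as_tensor(value), self.params["mu"], self.params["sigma"]
        return switch(v > 0, pt.log_ndtr((pt.log(v) - mu) / sigma), NEG_INF)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        return rng.lognormal(pvals["mu"], pvals["sigma"],
                             size=self._pshape(size, pvals))

    def initial_value(self, pvals):
        # median: stays O(1) even for large sigma
        return np.broadcast_to(np.exp(np.asarray(pvals["mu"], dtype=float)),
                               self._pshape(None, pvals)).copy()

    def validate(self, pvals):
        _check(np.all(np.asarray(pvals["sigma"]) > 0), "LogNormal: sigma must be > 0")


class Gamma(DistributionSpec):
    family = "Gamma"
    param_names = ("alpha", "beta")

    def __init__(self, alpha, beta):
        super().__init__(alpha=alpha, beta=beta)

    support = Support(lower=0.0)

    def logp(self, value):
        v = as_tensor(value)
        a, b = self.params["alpha"], self.params["beta"]
        inside = a * pt.log(b) - pt.gammaln(a) + (a - 1.0) * pt.log(v) - b * v
        return switch(v > 0, inside, NEG_INF)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        return rng.gamma(pvals["alpha"],
                         1.0 / np.asarray(pvals["beta"], dtype=float),
                         size=self._pshape(size, pvals))

    def initial_value(self, pvals):
        a = np.asarray(pvals["alpha"], dtype=float)
        b = np.asarray(pvals["beta"], dtype=float)
        return np.broadcast_to(a / b, self._pshape(None, pvals)).copy()

    def validate(self, pvals):
        _check(np.all(np.asarray(pvals["alpha"]) > 0) and
               np.all(np.asarray(pvals["beta"]) > 0),
               "Gamma: alpha and beta must be > 0")


class Dirichlet(DistributionSpec):
    family = "Dirichlet"
    param_names = ("a",)
    event_params = ("a",)

    def __init__(self, a):
        super().__init__(a=a)

    support = Support(lower=0.0, upper=1.0, simplex=True, event_rank=1)

    def logp(self, value):
        v, a = as_tensor(value), self.params["a"]
        inside = pt.sum_((a - 1.0) * pt.log(v), axis=-1) \
            + pt.gammaln(pt.sum_(a, axis=-1)) - pt.sum_(pt.gammaln(a), axis=-1)
        ok = pt.prod_(v > 0, axis=-1)
        return switch(ok, inside, NEG_INF)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        a = np.asarray(pvals["a"], dtype=float)
        batch = self._pshape(size, pvals)
        if a.ndim == 1 and not batch:
            return rng.dirichlet(a)
        flat = int(np.prod(batch)) if batch else 1
        a2 = np.broadcast_to(a, tuple(batch) + (a.shape[-1],)).reshape(flat, -1)
        out = np.stack([rng.dirichlet(row) for row in a2])
        return out.reshape(tuple(batch) + (a.shape[-1],))

    def initial_value(self, pvals):
        a = np.asarray(pvals["a"], dtype=float)
        return a / a.sum(axis=-1, keepdims=True)

    def validate(self, pvals):
        _check(np.all(np.asarray(pvals["a"]) > 0), "Dirichlet: a must be > 0")


# ---------------------------------------------------------------------------
# Discrete families
# ---------------------------------------------------------------------------


class Bernoulli(DistributionSpec):
    """Bernoulli with either a probability ``p`` or log-odds ``logit_p``."""

    family = "Bernoulli"
    param_names = ("p",)

    def __init__(self, p=None, logit_p=None):
        if (p is None) == (logit_p is None):
            raise ParameterError("Bernoulli: give exactly one of p, logit_p")
        self._logit = logit_p is not None
        super().__init__(p=logit_p if self._logit else p)

    support = Support(continuous=False, lower=0.0, upper=1.0)

    def _prob_node(self):
        raw = self.params["p"]
        return pt.logistic(raw) if self._logit else raw

    def logp(self, value):
        v = as_tensor(value)
        raw = self.params["p"]
        if self._logit:
            inside = v * raw - pt.softplus(raw)
        else:
            inside = v * pt.log(raw) + (1.0 - v) * pt.log1p(-raw)
        ok = pt.eq(v, 0.0) + pt.eq(v, 1.0)
        return switch(ok, inside, NEG_INF)

    def _prob_val(self, pvals):
        from scipy.special import expit
        raw = np.asarray(pvals["p"], dtype=float)
        return expit(raw) if self._logit else raw

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        p = self._prob_val(pvals)
        return rng.binomial(1, p, size=self._pshape(size, pvals))

    def initial_value(self, pvals):
        p = self._prob_val(pvals)
        return np.broadcast_to(np.round(p), self._pshape(None, pvals)).copy()

    def validate(self, pvals):
        if not self._logit:
            p = np.asarray(pvals["p"])
            _check(np.all((p >= 0) & (p <= 1)), "Bernoulli: p must be in [0, 1]")


class Binomial(DistributionSpec):
    family = "Binomial"
    param_names = ("n", "p")

    def __init__(self, n, p):
        super().__init__(n=n, p=p)

    support = Support(continuous=False, lower=0.0)

    def logp(self, value):
        v = as_tensor(value)
        n, p = self.params["n"], self.params["p"]
        inside = pt.gammaln(n + 1.0) - pt.gammaln(v + 1.0) \
            - pt.gammaln(n - v + 1.0) + v * pt.log(p) + (n - v) * pt.log1p(-p)
        ok = (v >= 0) * (v <= n)
        return switch(ok, inside, NEG_INF)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        return rng.binomial(pvals["n"], pvals["p"],
                            size=self._pshape(size, pvals))

    def initial_value(self, pvals):
        n = np.asarray(pvals["n"], dtype=float)
        p = np.asarray(pvals["p"], dtype=float)
        return np.broadcast_to(np.round(n * p), self._pshape(None, pvals)).copy()

    def validate(self, pvals):
        p = np.asarray(pvals["p"])
        _check(np.all((p >= 0) & (p <= 1)), "Binomial: p must be in [0, 1]")
        _check(np.all(np.asarray(pvals["n"]) >= 0), "Binomial: n must be >= 0")


class Poisson(DistributionSpec):
    family = "Poisson"
    param_names = ("mu",)

    def __init__(self, mu):
        super().__init__(mu=mu)

    support = Support(continuous=False, lower=0.0)

    def logp(self, value):
        v, mu = as_tensor(value), self.params["mu"]
        inside = v * pt.log(mu) - mu - pt.gammaln(v + 1.0)
        return switch(v >= 0, inside, NEG_INF)

    def logcdf(self, value):
        v, mu = as_tensor(value), self.params["mu"]
        inside = pt.log(pt.apply_op("gammaincc", pt.floor_(v) + 1.0, mu))
        return switch(v >= 0, inside, NEG_INF)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        return rng.poisson(pvals["mu"], size=self._pshape(size, pvals))

    def initial_value(self, pvals):
        mu = np.asarray(pvals["mu"], dtype=float)
        return np.broadcast_to(np.floor(mu), self._pshape(None, pvals)).copy()

    def validate(self, pvals):
        _check(np.all(np.asarray(pvals["mu"]) >= 0), "Poisson: mu must be >= 0")


class DiscreteUniform(DistributionSpec):
    family = "DiscreteUniform"
    param_names = ("lower", "upper")

    def __init__(self, lower, upper):
        super().__init__(lower=lower, upper=upper)

    @property
    def support(self):
        lo = self.params["lower"]
        hi = self.params["upper"]
        return Support(continuous=False,
                       lower=float(lo.value) if lo.kind == "constant" else -np.inf,
                       upper=float(hi.value) if hi.kind == "constant" else np.inf)

    def logp(self, value):
        v = as_tensor(value)
        l, u = self.params["lower"], self.params["upper"]
        ok = (v >= l) * (v <= u)
        return switch(ok, -pt.log(u - l + 1.0), NEG_INF)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        return rng.integers(int(pvals["lower"]), int(pvals["upper"]) + 1,
                            size=self._pshape(size, pvals))

    def initial_value(self, pvals):
        l = np.asarray(pvals["lower"], dtype=float)
        u = np.asarray(pvals["upper"], dtype=float)
        return np.broadcast_to(np.floor((l + u) / 2.0),
                               self._pshape(None, pvals)).copy()

    def validate(self, pvals):
        _check(np.all(np.asarray(pvals["lower"]) <= np.asarray(pvals["upper"])),
               "DiscreteUniform: lower must be <= upper")


class Multinomial(DistributionSpec):
    family = "Multinomial"
    param_names = ("n", "p")
    event_params = ("p",)

    def __init__(self, n, p):
        super().__init__(n=n, p=p)

    support = Support(continuous=False, lower=0.0, event_rank=1)

    def logp(self, value):
        v = as_tensor(value)
        n, p = self.params["n"], self.params["p"]
        return pt.gammaln(n + 1.0) - pt.sum_(pt.gammaln(v + 1.0), axis=-1) \
            + pt.sum_(v * pt.log(p), axis=-1)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        n = np.asarray(pvals["n"])
        p = np.asarray(pvals["p"], dtype=float)
        batch = self._pshape(size, pvals)
        if not batch:
            return rng.multinomial(int(n), p)
        flat = int(np.prod(batch))
        n2 = np.broadcast_to(n, batch).reshape(flat)
        p2 = np.broadcast_to(p, tuple(batch) + (p.shape[-1],)).reshape(flat, -1)
        out = np.stack([rng.multinomial(int(ni), pi) for ni, pi in zip(n2, p2)])
        return out.reshape(tuple(batch) + (p.shape[-1],))

    def initial_value(self, pvals):
        n = np.asarray(pvals["n"], dtype=float)
        p = np.asarray(pvals["p"], dtype=float)
        return np.floor(n[..., None] * p) if np.ndim(n) else np.floor(n * p)

    def validate(self, pvals):
        p = np.asarray(pvals["p"])
        _check(np.all(p >= 0) and np.all(np.abs(p.sum(axis=-1) - 1) < 1e-8),
               "Multinomial: p must be a probability vector")


class DirichletMultinomial(DistributionSpec):
    """Dirichlet-compound multinomial (Polya) counts.

    The Dirichlet mixing is marginalized into the closed-form mass
    ``C(n; x) * B(x + a) / B(a)`` expressed through log-gamma terms, which
    makes the family over-dispersed relative to a multinomial with the same
    mean: variance is inflated by ``(n + a0) / (1 + a0)`` with
    ``a0 = sum(a)``.
    """

    family = "DirichletMultinomial"
    param_names = ("n", "a")
    event_params = ("a",)

    def __init__(self, n, a):
        super().__init__(n=n, a=a)

    support = Support(continuous=False, lower=0.0, event_rank=1)

    def logp(self, value):
        v = as_tensor(value)
        n, a = self.params["n"], self.params["a"]
        a0 = pt.sum_(a, axis=-1)
        return pt.gammaln(n + 1.0) + pt.gammaln(a0) - pt.gammaln(n + a0) \
            + pt.sum_(pt.gammaln(v + a) - pt.gammaln(a)
                      - pt.gammaln(v + 1.0), axis=-1)

    def sample(self, rng, size, pvals):
        self.validate(pvals)
        n = np.asarray(pvals["n"])
        a = np.asarray(pvals["a"], dtype=float)
        batch = self._pshape(size, pvals)
        if not batch:
            return rng.multinomial(int(n), rng.dirichlet(a))
        flat = int(np.prod(batch))
        n2 = np.broadcast_to(n, batch).reshape(flat)
        a2 = np.broadcast_to(a, tuple(batch) + (a.shape[-1],)).reshape(flat, -1)
        out = np.stack([rng.multinomial(int(ni), rng.dirichlet(ai))
                        for ni, ai in zip(n2, a2)])
        return out.reshape(tuple(batch) + (a.shape[-1],))

    def initial_value(self, pvals):
        n = np.asarray(pvals["n"], dtype=float)
        a = np.asarray(pvals["a"], dtype=float)
        frac = a / a.sum(axis=-1, keepdims=True)
        return np.floor((n[..., None] if np.ndim(n) else n) * frac)

    def validate(self, pvals):
        _check(np.all(np.asarray(pvals["a"]) > 0),
               "DirichletMultinomial: a must be > 0")


# ---------------------------------------------------------------------------
# Censoring / truncation wrappers
# ---------------------------------------------------------------------------


class Censored(DistributionSpec):
    """Censoring wrapper: probability mass outside the bounds lumps onto them.

    ``logp`` equals the base log-CDF at the lower bound, the base log
    survival at the upper bound, the base logp strictly inside, and ``-inf``
    outside.  Requires the base family's logcdf whenever a bound is finite.
    """

    family = "Censored"
    param_names = ()

    def __init__(self, base: DistributionSpec, lower=-np.inf, upper=np.inf):
        super().__init__()
        self.base = base
        self.lower = float(lower)
        self.upper = float(upper)
        if (np.isfinite(self.lower) or np.isfinite(self.upper)):
            try:
                base.logcdf(constant(0.0))
            except UnsupportedOperationError:
                raise UnsupportedOperationError(
                    f"Censored with a finite bound needs {base.family}.logcdf")

    @property
    def support(self):
        s = self.base.support
        return Support(continuous=s.continuous,
                       lower=max(s.lower, self.lower),
                       upper=min(s.upper, self.upper),
                       event_rank=s.event_rank)

    def logp(self, value):
        v = as_tensor(value)
        out = self.base.logp(v)
        if np.isfinite(self.lower):
            out = switch(pt.eq(v, self.lower),
                         self.base.logcdf(constant(self.lower)), out)
            out = switch(v < self.lower, NEG_INF, out)
        if np.isfinite(self.upper):
            out = switch(pt.eq(v, self.upper),
                         _log1mexp(self.base.logcdf(constant(self.upper))), out)
            out = switch(v > self.upper, NEG_INF, out)
        return out

    def sample(self, rng, size, pvals):
        raw = self.base.sample(rng, size, pvals)
        return np.clip(raw, self.lower, self.upper)

    def initial_value(self, pvals):
        return np.clip(self.base.initial_value(pvals), self.lower, self.upper)

    def param_rank(self):
        return self.base.param_rank()

    def _pshape(self, size, pvals):
        return self.base._pshape(size, pvals)

    def validate(self, pvals):
        self.base.validate(pvals)

    def __repr__(self):
        return f"Censored({self.base!r}, [{self.lower:.2g}, {self.upper:.2g}])"


class Truncated(DistributionSpec):
    """Truncation wrapper: the base density renormalized to [lower, upper]."""

    family = "Truncated"
    param_names = ()

    def __init__(self, base: DistributionSpec, lower=-np.inf, upper=np.inf):
        super().__init__()
        self.base = base
        self.lower = float(lower)
        self.upper = float(upper)
        if np.isfinite(self.lower) or np.isfinite(self.upper):
            try:
                base.logcdf(constant(0.0))
            except UnsupportedOperationError:
                raise UnsupportedOperationError(
                    f"Truncated with a finite bound needs {base.family}.logcdf")

    @property
    def support(self):
        s = self.base.support
        return Support(continuous=s.continuous,
                       lower=max(s.lower, self.lower),
                       upper=min(s.upper, self.upper),
                       event_rank=s.event_rank)

    def _log_norm(self):
        lo_finite = np.isfinite(self.lower)
        hi_finite = np.isfinite(self.upper)
        if lo_finite and hi_finite:
            lu = self.base.logcdf(constant(self.upper))
            ll = self.base.logcdf(constant(self.lower))
            return lu + _log1mexp(ll - lu)
        if hi_finite:
            return self.base.logcdf(constant(self.upper))
        if lo_finite:
            return _log1mexp(self.base.logcdf(constant(self.lower)))
        return constant(0.0)

    def logp(self, value):
        v = as_tensor(value)
        inside = self.base.logp(v) - self._log_norm()
        ok = (v >= constant(self.lower)) * (v <= constant(self.upper))
        return switch(ok, inside, NEG_INF)

    def sample(self, rng, size, pvals, max_tries=1000):
        shape = self.base._pshape(size, pvals)
        out = self.base.sample(rng, size, pvals)
        out = np.asarray(out, dtype=float)
        bad = (out < self.lower) | (out > self.upper)
        for _ in range(max_tries):
            if not np.any(bad):
                break
            redraw = self.base.sample(rng, size, pvals)
            out = np.where(bad, redraw, out)
            bad = (out < self.lower) | (out > self.upper)
        else:
            raise RuntimeError("Truncated.sample: rejection sampling stalled")
        return out.reshape(shape) if shape else out

    def initial_value(self, pvals):
        init = np.asarray(self.base.initial_value(pvals), dtype=float)
        lo, hi = self.lower, self.upper
        mid = np.where((init > lo) & (init < hi), init,
                       np.clip(init, lo, hi))
        if np.isfinite(lo) and np.isfinite(hi):
            mid = np.where((mid <= lo) | (mid >= hi), (lo + hi) / 2.0, mid)
        elif np.isfinite(lo):
            mid = np.where(mid <= lo, lo + 1.0, mid)
        elif np.isfinite(hi):
            mid = np.where(mid >= hi, hi - 1.0, mid)
        return mid

    def param_rank(self):
        return self.base.param_rank()

    def _pshape(self, size, pvals):
        return self.base._pshape(size, pvals)

    def validate(self, pvals):
        self.base.validate(pvals)

    def __repr__(self):
        return f"Truncated({self.base!r}, [{self.lower:.2g}, {self.upper:.2g}])"


# ---------------------------------------------------------------------------
# Module-level helpers
# ---------------------------------------------------------------------------


def logp(rv: RandomVariableNode | DistributionSpec, value) -> TensorNode:
    """Symbolic log-density of a random variable at ``value``."""
    dist = rv.dist if isinstance(rv, RandomVariableNode) else rv
    return dist.logp(value)


def logcdf(rv: RandomVariableNode | DistributionSpec, value) -> TensorNode:
    dist = rv.dist if isinstance(rv, RandomVariableNode) else rv
    return dist.logcdf(value)


def default_initial_value(dist: DistributionSpec, pvals=None):
    """A point of positive density, from numeric parameter values."""
    if pvals is None:
        pvals = {k: np.asarray(v.value)
                 for k, v in dist.params.items() if v.kind == "constant"}
    return dist.initial_value(pvals)


def _eval_param_nodes(dist: DistributionSpec, vals: dict):
    out = {}
    for k in dist.param_names:
        out[k] = vals[dist.params[k].nid]
    return out


def draw(node, draws: int = 1, seed=None):
    """Seeded ancestral sampling through any graph containing RV nodes.

    Returns an array with a leading ``draws`` axis.  Each distinct RV node
    gets an independent substream spawned from the root seed, in stable
    topological order, so the same seed reproduces the same output and
    adding unrelated variables does not perturb existing ones.
    """
    node = as_tensor(node)
    order = pt.topological_order([node])
    rv_nodes = [n for n in order if isinstance(n, RandomVariableNode)]
    ss = np.random.SeedSequence(seed)
    streams = {rv.nid: np.random.default_rng(child)
               for rv, child in zip(rv_nodes, ss.spawn(max(len(rv_nodes), 1)))}
    results = []
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for _ in range(int(draws)):
            vals: dict[int, np.ndarray] = {}
            for n in order:
                if isinstance(n, RandomVariableNode):
                    pvals = _eval_param_nodes(n.dist, vals)
                    vals[n.nid] = np.asarray(
                        n.dist.sample(streams[n.nid], n.size, pvals))
                elif n.kind == "constant":
                    vals[n.nid] = n.value
                elif n.kind == "apply":
                    vals[n.nid] = pt._eval_apply(
                        n.op, [vals[c.nid] for c in n.inputs], n.params)
                else:
                    raise pt.UnboundInputError(
                        f"draw: unbound input {n.name or n.nid!r} in graph")
            results.append(np.asarray(vals[node.nid]))
    return np.stack(results)
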