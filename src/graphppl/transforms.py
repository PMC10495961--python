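"""Change-of-variable transforms to unconstrained space.

Gradient-based samplers work on an unconstrained reparameterization of each
bounded free variable; the joint log-density then needs the log absolute
Jacobian determinant of the backward (unconstrained -> constrained) map.
Three transforms cover the shipped families:

* ``log`` for positive-support continuous variables (optionally shifted for
  a nonzero lower bound): ``u = log(x - lower)``, log-Jacobian ``u``.
* ``interval(a, b)`` for doubly-bounded variables, the scaled log-odds map
  ``u = log((x - a) / (b - x))``; backward is ``a + (b - a) * sigmoid(u)``
  with log-Jacobian ``log(b - a) - softplus(u) - softplus(-u)``.
* ``simplex`` for Dirichlet vectors, the stick-breaking map with ``K - 1``
  unconstrained coordinates, centered so the all-zeros vector maps to the
  uniform simplex point.

Transforms are used for sampling only; traces and user-facing draws report
constrained values.
"""

from __future__ import annotations

import math

import numpy as np

from . import tensor as pt
from .tensor import TensorNode, as_tensor, constant

__all__ = [
    "Transform", "LogTransform", "IntervalTransform", "SimplexTransform",
    "assign_default_transform", "transformed_name", "parse_transformed_name",
    "log_jac_term",
]

_SUFFIXES = {"log": "_log__", "interval": "_interval__", "simplex": "_simplex__"}


def transformed_name(base: str, transform: "Transform | None") -> str:
    if transform is None:
        return base
    return base + _SUFFIXES[transform.tag]


def parse_transformed_name(name: str) -> tuple[str, str | None]:
    """Invert the suffix convention: returns (base name, transform tag)."""
    for tag, suffix in _SUFFIXES.items():
        if name.endswith(suffix):
            return name[: -len(suffix)], tag
    return name, None


class Transform:
    """Bijection constrained <-> unconstrained, as symbolic graph maps."""

    tag: str

    def forward(self, x: TensorNode) -> TensorNode:
        """Constrained -> unconstrained."""
        raise NotImplementedError

    def backward(self, u: TensorNode) -> TensorNode:
        """Unconstrained -> constrained."""
        raise NotImplementedError

    def log_jac(self, u: TensorNode) -> TensorNode:
        """Elementwise log |d backward / d u| (summed by the caller)."""
        raise NotImplementedError

    def forward_value(self, x) -> np.ndarray:
        return np.asarray(self.forward(constant(x)).eval({}), dtype=float)

    def backward_value(self, u) -> np.ndarray:
        return np.asarray(self.backward(constant(u)).eval({}), dtype=float)

    def unconstrained_shape(self, shape: tuple) -> tuple:
        return shape

    def backward_array(self, u: np.ndarray) -> np.ndarray:
        """Vectorized numeric backward map (batched over leading axes)."""
        raise NotImplementedError

    def __repr__(self):
        return f"<{type(self).__name__}>"


class LogTransform(Transform):
    tag = "log"

    def __init__(self, lower: float = 0.0):
        self.lower = float(lower)

    def forward(self, x):
        x = as_tensor(x)
        return pt.log(x - self.lower) if self.lower != 0.0 else pt.log(x)

    def backward(self, u):
        u = as_tensor(u)
        return pt.exp(u) + self.lower if self.lower != 0.0 else pt.exp(u)

    def log_jac(self, u):
        return as_tensor(u)

    def backward_array(self, u):
        return np.exp(np.asarray(u, dtype=float)) + self.lower


class IntervalTransform(Transform):
    tag = "interval"

    def __init__(self, lower: float, upper: float):
        self.lower = float(lower)
        self.upper = float(upper)
        if not (np.isfinite(lower) and np.isfinite(upper) and lower < upper):
            raise ValueError("interval transform needs finite lower < upper")

    def forward(self, x):
        x = as_tensor(x)
        return pt.log((x - self.lower) / (self.upper - x))

    def backward(self, u):
        u = as_tensor(u)
        width = self.upper - self.lower
        return constant(self.lower) + constant(width) * pt.logistic(u)

    def log_jac(self, u):
        u = as_tensor(u)
        return constant(math.log(self.upper - self.lower)) \
            - pt.softplus(u) - pt.softplus(-u)

    def backward_array(self, u):
        from scipy.special import expit
        return self.lower + (self.upper - self.lower) * expit(
            np.asarray(u, dtype=float))


class SimplexTransform(Transform):
    """Centered stick-breaking between the K-simplex and R^(K-1)."""

    tag = "simplex"

    def __init__(self, k: int):
        if k < 2:
            raise ValueError("simplex transform needs K >= 2")
        self.k = int(k)

    def unconstrained_shape(self, shape):
        return shape[:-1] + (self.k - 1,)

    def _offsets(self):
        # u = 0 maps to the uniform point: offset log(1 / (K - k)) per stick
        return [-math.log(self.k - i - 1) for i in range(self.k - 1)]

    def backward(self, u):
        u = as_tensor(u)
        offs = self._offsets()
        parts = []
        remaining = constant(1.0)
        for i in range(self.k - 1):
            z = pt.logistic(pt.take(u, i) + offs[i])
            x_i = z * remaining
            parts.append(x_i)
            remaining = remaining - x_i
        parts.append(remaining)
        # assemble into a vector via put on a zero constant
        out = constant(np.zeros(self.k))
        for i, p in enumerate(parts):
            out = out + p * constant(np.eye(self.k)[i])
        return out

    def forward(self, x):
        x = as_tensor(x)
        offs = self._offsets()
        us = []
        remaining = constant(1.0)
        for i in range(self.k - 1):
            x_i = pt.take(x, i)
            z = x_i / remaining
            us.append(pt.log(z / (1.0 - z)) - offs[i])
            remaining = remaining - x_i
        out = constant(np.zeros(self.k - 1))
        for i, u in enumerate(us):
            out = out + u * constant(np.eye(self.k - 1)[i])
        return out

    def backward_array(self, u):
        from scipy.special import expit
        u = np.asarray(u, dtype=float)
        offs = np.asarray(self._offsets())
        out = np.zeros(u.shape[:-1] + (self.k,))
        remaining = np.ones(u.shape[:-1])
        for i in range(self.k - 1):
            z = expit(u[..., i] + offs[i])
            out[..., i] = z * remaining
            remaining = remaining - out[..., i]
        out[..., -1] = remaining
        return out

    def log_jac(self, u):
        u = as_tensor(u)
        offs = self._offsets()
        total = constant(0.0)
        remaining = constant(1.0)
        for i in range(self.k - 1):
            t = pt.take(u, i) + offs[i]
            z = pt.logistic(t)
            # d x_i / d u_i = z (1 - z) * remaining
            total = total - pt.softplus(t) - pt.softplus(-t) + pt.log(remaining)
            remaining = remaining - z * remaining
        return total


def assign_default_transform(dist) -> Transform | None:
    """Pick the standard unconstraining transform from support metadata.

    Positive continuous -> log; doubly-bounded continuous -> interval;
    simplex -> stick-breaking; unbounded continuous and all discrete
    families (including DiscreteUniform) -> none.
    """
    s = dist.support
    if not s.continuous:
        return None
    if s.simplex:
        a = dist.params.get("a")
        if a is not None and a.kind == "constant":
            k = int(np.asarray(a.value).shape[-1])
        else:
            raise ValueError("simplex transform needs a constant-length event")
        return SimplexTransform(k)
    lo_f, hi_f = np.isfinite(s.lower), np.isfinite(s.upper)
    if lo_f and hi_f:
        return IntervalTransform(s.lower, s.upper)
    if lo_f:
        return LogTransform(s.lower)
    if hi_f:
        # mirrored log map for upper-bounded support
        class _NegLog(LogTransform):
            def forward(self, x):
                return pt.log(constant(s.upper) - as_tensor(x))

            def backward(self, u):
                return constant(s.upper) - pt.exp(as_tensor(u))
        return _NegLog()
    return None


def log_jac_term(transform: Transform | None, unconstrained) -> np.ndarray:
    """Numeric log |d backward / d u| at an unconstrained point."""
    if transform is None:
        return np.zeros(np.shape(unconstrained))
    node = transform.log_jac(pt.constant(np.asarray(unconstrained, dtype=float)))
    return np.asarray(node.eval({}))
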