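"""The probabilistic model container.

A :class:`ProbModel` ties together named free (latent) random variables,
observed variables (with automatic missing-value splitting), deterministic
nodes, and dimension/coordinate labels, and assembles the Jacobian-corrected
joint log-density over the transformed free variables.

Observed arrays may contain NaN markers: the data is partitioned into an
observed part and a missing part, the missing part becomes a free variable
whose prior is the likelihood family itself, and both are recombined into a
deterministic node carrying the original name (so traces and predictive
draws report the full-length vector).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from . import tensor as pt
from . import distributions as dist_mod
from .distributions import DistributionSpec, RandomVariableNode
from . import transforms as tr
from .transforms import Transform, assign_default_transform, transformed_name

__all__ = ["ProbModel", "FreeVar", "ObservedVar", "joint_logp"]


@dataclass
class FreeVar:
    name: str
    rv: RandomVariableNode
    transform: Transform | None
    initval: Any = None
    dims: tuple[str, ...] | None = None
    #: False for missing-data variables whose prior term is carried by the
    #: observed full-vector likelihood instead.
    own_prior_term: bool = True
    value_node: pt.TensorNode | None = None
    constrained_node: pt.TensorNode | None = None

    @property
    def transformed(self) -> str:
        return transformed_name(self.name, self.transform)


@dataclass
class ObservedVar:
    name: str
    rv: RandomVariableNode
    data: np.ndarray           # full array, NaN at missing positions
    mask: np.ndarray           # True where missing
    dims: tuple[str, ...] | None = None
    obs_idx: np.ndarray | None = None
    mis_idx: np.ndarray | None = None
    missing_name: str | None = None

    @property
    def display_name(self) -> str:
        return f"{self.name}_observed" if self.mask.any() else self.name

    @property
    def n_observed(self) -> int:
        return int((~self.mask).sum())

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())


def _eval_with_rvs(nodes, rv_values: dict[int, np.ndarray]):
    """Evaluate graph nodes where RV leaves take the given numeric values."""
    order = pt.topological_order(list(nodes))
    vals: dict[int, Any] = {}
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for n in order:
            if n.nid in rv_values:
                vals[n.nid] = np.asarray(rv_values[n.nid])
            elif isinstance(n, RandomVariableNode):
                raise ValueError(
                    f"value of upstream variable {n.name!r} is not known yet; "
                    "declare parents before children")
            elif n.kind == "constant":
                vals[n.nid] = n.value
            elif n.kind == "apply":
                vals[n.nid] = pt._eval_apply(
                    n.op, [vals[c.nid] for c in n.inputs], n.params)
            else:
                raise pt.UnboundInputError(
                    f"unbound input {n.name or n.nid!r} in model graph")
    return [vals[n.nid] for n in nodes]


class ProbModel:
    """Registry of free/observed/deterministic variables with coords.

    The model is an explicit builder: variables are added with
    :meth:`add_free`, :meth:`add_observed` and :meth:`add_deterministic`, in
    dependency order (a random variable used as a parameter of a later one
    establishes the parent-child edge).
    """

    def __init__(self, coords: dict[str, Sequence] | None = None):
        self.coords: dict[str, np.ndarray] = {
            k: np.asarray(v) for k, v in (coords or {}).items()}
        self.free: dict[str, FreeVar] = {}
        self.observed: dict[str, ObservedVar] = {}
        self.deterministics: dict[str, pt.TensorNode] = {}
        self.det_dims: dict[str, tuple[str, ...] | None] = {}
        self._logp_cache: dict = {}

    # -- registration -------------------------------------------------------

    def _check_name(self, name: str):
        if name in self.free or name in self.observed \
                or name in self.deterministics:
            raise ValueError(f"variable name {name!r} already in use")

    def _resolve_dims(self, dims) -> tuple[tuple[str, ...] | None, tuple | None]:
        if dims is None:
            return None, None
        if isinstance(dims, str):
            dims = (dims,)
        shape = []
        for d in dims:
            if d not in self.coords:
                raise KeyError(f"unknown dimension {d!r}; add it to coords")
            shape.append(len(self.coords[d]))
        return tuple(dims), tuple(shape)

    def add_free(self, name: str, dist: DistributionSpec, dims=None,
                 shape=None, initval=None, transform="default"
                 ) -> RandomVariableNode:
        """Register a latent random variable; returns its graph node."""
        self._check_name(name)
        dims_t, dim_shape = self._resolve_dims(dims)
        if dim_shape is not None:
            shape = dim_shape[: len(dim_shape) - dist.support.event_rank] or None
        if shape is not None and np.isscalar(shape):
            shape = (int(shape),)
        rv = RandomVariableNode(dist, name=name, size=shape)
        t = assign_default_transform(dist) if transform == "default" else transform
        self.free[name] = FreeVar(name, rv, t, initval=initval, dims=dims_t)
        self._logp_cache.clear()
        return rv

    def add_observed(self, name: str, dist: DistributionSpec, observed,
                     dims=None) -> RandomVariableNode:
        """Register an observed variable; NaN entries become imputed latents."""
        self._check_name(name)
        dims_t, dim_shape = self._resolve_dims(dims)
        if hasattr(observed, "values"):
            observed = observed.values
        data = np.asarray(observed, dtype=float)
        if dim_shape is not None and data.shape != dim_shape:
            raise ValueError(
                f"observed data shape {data.shape} does not match dims shape "
                f"{dim_shape} for {name!r}")
        mask = np.isnan(data)
        rv = RandomVariableNode(dist, name=name,
                                size=data.shape[: data.ndim - dist.support.event_rank]
                                or None)
        ov = ObservedVar(name, rv, data, mask, dims=dims_t)
        if mask.any():
            if dist.support.event_rank:
                raise NotImplementedError(
                    "missing values in multivariate observations")
            if data.ndim != 1:
                raise NotImplementedError("missing-value split needs 1-D data")
            ov.mis_idx = np.flatnonzero(mask)
            ov.obs_idx = np.flatnonzero(~mask)
            ov.missing_name = f"{name}_missing"
            mis_dist = copy.copy(dist)
            mis_dist.params = {
                k: (pt.take(v, ov.mis_idx) if (v.rank or 0) >= 1 else v)
                for k, v in dist.params.items()}
            mis_rv = RandomVariableNode(mis_dist, name=ov.missing_name,
                                        size=(len(ov.mis_idx),))
            self.free[ov.missing_name] = FreeVar(
                ov.missing_name, mis_rv,
                assign_default_transform(mis_dist),
                dims=None, own_prior_term=False)
        self.observed[name] = ov
        self._logp_cache.clear()
        return rv

    def add_deterministic(self, name: str, node: pt.TensorNode,
                          dims=None) -> pt.TensorNode:
        """Name and trace a derived quantity (adds no probability)."""
        self._check_name(name)
        dims_t, _ = self._resolve_dims(dims)
        node = pt.as_tensor(node)
        if node.name is None:
            node.name = name
        self.deterministics[name] = node
        self.det_dims[name] = dims_t
        self._logp_cache.clear()
        return node

    # -- accessors -----------------------------------------------------------

    @property
    def free_RVs(self) -> list[RandomVariableNode]:
        return [fv.rv for fv in self.free.values()]

    @property
    def observed_RVs(self) -> list[RandomVariableNode]:
        return [ov.rv for ov in self.observed.values()]

    @property
    def basic_RVs(self) -> list[RandomVariableNode]:
        return self.free_RVs + self.observed_RVs

    @property
    def continuous_vars(self) -> list[FreeVar]:
        return [fv for fv in self.free.values() if fv.rv.dist.support.continuous]

    @property
    def discrete_vars(self) -> list[FreeVar]:
        return [fv for fv in self.free.values()
                if not fv.rv.dist.support.continuous]

    def var_shape(self, fv: FreeVar) -> tuple:
        """Constrained shape of a free variable."""
        rv = fv.rv
        ev = rv.dist.support.event_rank
        if rv.size is not None:
            batch = rv.size
        else:
            batch = ()
        if ev:
            a = rv.dist.params.get("a") or rv.dist.params.get("p")
            k = int(np.asarray(a.value).shape[-1]) if a is not None \
                and a.kind == "constant" else None
            return tuple(batch) + ((k,) if k else ())
        if rv.size is None and rv.dist.param_rank() > 0:
            pv = self._init_param_values(fv)
            return rv.dist._pshape(None, pv)
        return tuple(batch)

    # -- joint density -------------------------------------------------------

    def _build_value_nodes(self):
        for fv in self.free.values():
            if fv.value_node is not None:
                continue
            rank = fv.rv.rank if fv.rv.rank is not None else 0
            fv.value_node = pt.make_input(rank, transformed_name(fv.name,
                                                                 fv.transform))
            if fv.transform is None:
                fv.constrained_node = fv.value_node
            else:
                fv.constrained_node = fv.transform.backward(fv.value_node)

    def _rv_substitution(self) -> dict[pt.TensorNode, pt.TensorNode]:
        self._build_value_nodes()
        return {fv.rv: fv.constrained_node for fv in self.free.values()}

    def observed_value_node(self, ov: ObservedVar) -> pt.TensorNode:
        """Data with missing entries replaced by the imputation variable."""
        if not ov.mask.any():
            return pt.constant(ov.data)
        self._build_value_nodes()
        base = pt.constant(np.where(ov.mask, 0.0, ov.data))
        missing = self.free[ov.missing_name].constrained_node
        return pt.put(base, ov.mis_idx, missing)

    def logp_terms(self, jacobian: bool = True):
        """Per-variable scalar contributions to the joint log-density."""
        self._build_value_nodes()
        sub = self._rv_substitution()
        terms: dict[str, pt.TensorNode] = {}
        for fv in self.free.values():
            if not fv.own_prior_term:
                continue
            lp = fv.rv.dist.logp(fv.constrained_node)
            lp = pt.clone_replace([lp], sub)[0]
            term = pt.sum_(lp)
            if jacobian and fv.transform is not None:
                term = term + pt.sum_(fv.transform.log_jac(fv.value_node))
            terms[fv.name] = term
        for ov in self.observed.values():
            value = self.observed_value_node(ov)
            lp = ov.rv.dist.logp(value)
            lp = pt.clone_replace([lp], sub)[0]
            terms[ov.name] = pt.sum_(lp)
        return terms

    def joint_logp(self, jacobian: bool = True) -> pt.TensorNode:
        """Scalar joint log-density node over transformed free values."""
        key = ("joint", jacobian)
        if key not in self._logp_cache:
            terms = list(self.logp_terms(jacobian=jacobian).values())
            if not terms:
                raise ValueError("model has no variables")
            total = terms[0]
            for t in terms[1:]:
                total = total + t
            self._logp_cache[key] = total
        return self._logp_cache[key]

    def value_inputs(self) -> dict[str, pt.TensorNode]:
        self._build_value_nodes()
        return {fv.transformed: fv.value_node for fv in self.free.values()}

    def compile_logp(self, jacobian: bool = True) -> pt.CompiledFunction:
        """Compile the joint log-density over a transformed-point dict."""
        key = ("clogp", jacobian)
        if key not in self._logp_cache:
            inputs = list(self.value_inputs().values())
            self._logp_cache[key] = pt.compile_fn(inputs,
                                                  [self.joint_logp(jacobian)])
        return self._logp_cache[key]

    def compile_dlogp(self, jacobian: bool = True):
        """Gradient w.r.t. continuous transformed variables; returns a
        callable point-dict -> {name: grad array}."""
        key = ("cdlogp", jacobian)
        if key not in self._logp_cache:
            self._build_value_nodes()
            cont = [fv for fv in self.free.values()
                    if fv.rv.dist.support.continuous]
            wrt = [fv.value_node for fv in cont]
            grads = pt.grad(self.joint_logp(jacobian), wrt)
            cf = pt.compile_fn(list(self.value_inputs().values()), grads)
            names = [fv.transformed for fv in cont]

            def dlogp(point: dict):
                out = cf(point)
                if len(names) == 1:
                    out = [out]
                return dict(zip(names, out))

            self._logp_cache[key] = dlogp
        return self._logp_cache[key]

    def compile_logp_grad(self, jacobian: bool = True):
        """Joint logp and its gradient over continuous vars in one pass."""
        key = ("clogpgrad", jacobian)
        if key not in self._logp_cache:
            self._build_value_nodes()
            cont = [fv for fv in self.free.values()
                    if fv.rv.dist.support.continuous]
            wrt = [fv.value_node for fv in cont]
            grads = pt.grad(self.joint_logp(jacobian), wrt)
            cf = pt.compile_fn(list(self.value_inputs().values()),
                               [self.joint_logp(jacobian)] + grads)
            names = [fv.transformed for fv in cont]

            def logp_grad(point: dict):
                out = cf(point)
                if not isinstance(out, list):
                    out = [out]
                return out[0], dict(zip(names, out[1:]))

            self._logp_cache[key] = logp_grad
        return self._logp_cache[key]

    # -- initial values ------------------------------------------------------

    def _init_param_values(self, fv_or_ov, known=None):
        known = known or {}
        dist = fv_or_ov.rv.dist
        nodes = [dist.params[k] for k in dist.param_names]
        vals = _eval_with_rvs(nodes, known)
        return dict(zip(dist.param_names, vals))

    def initial_point(self, jitter: bool = False, seed=None
                      ) -> dict[str, np.ndarray]:
        """Per-variable starting values in transformed space.

        Defaults are family moments (means or medians) unless an ``initval``
        was given; with ``jitter`` a Uniform(-1, 1) perturbation is added to
        each continuous coordinate in transformed space.
        """
        rng = np.random.default_rng(seed)
        known: dict[int, np.ndarray] = {}
        point: dict[str, np.ndarray] = {}
        for fv in self.free.values():
            pvals = self._init_param_values(fv, known)
            if fv.initval is not None:
                shape = self.var_shape(fv)
                init = np.broadcast_to(
                    np.asarray(fv.initval, dtype=float), shape).copy() \
                    if shape else np.asarray(fv.initval, dtype=float)
                lp = _eval_with_rvs(
                    [fv.rv.dist.logp(pt.constant(init))], known | {
                        fv.rv.dist.params[k].nid: v for k, v in pvals.items()})
                if not np.all(np.isfinite(lp[0])):
                    raise ValueError(
                        f"initval for {fv.name!r} is outside the support")
            else:
                init = np.asarray(fv.rv.dist.initial_value(pvals), dtype=float)
                shape = self.var_shape(fv)
                if shape and init.shape != shape:
                    init = np.broadcast_to(init, shape).copy()
            known[fv.rv.nid] = init
            if fv.transform is None:
                u = np.asarray(init, dtype=float)
            else:
                u = fv.transform.forward_value(init)
            if jitter and fv.rv.dist.support.continuous:
                u = u + rng.uniform(-1.0, 1.0, size=np.shape(u))
            point[fv.transformed] = u + 0.0
        return point

    # -- DOT export ----------------------------------------------------------

    def _parents_of(self, roots: Sequence[pt.TensorNode]) -> list[str]:
        """Named model variables reachable from ``roots`` without passing
        through another named variable."""
        det_by_nid = {node.nid: name for name, node in self.deterministics.items()}
        rv_by_nid = {}
        for fv in self.free.values():
            rv_by_nid[fv.rv.nid] = fv.name
        for ov in self.observed.values():
            rv_by_nid[ov.rv.nid] = ov.name
        out, seen, stack = [], set(), list(roots)
        while stack:
            n = stack.pop()
            if n.nid in seen:
                continue
            seen.add(n.nid)
            if n.nid in det_by_nid:
                out.append(det_by_nid[n.nid])
                continue
            if n.nid in rv_by_nid:
                out.append(rv_by_nid[n.nid])
                continue
            stack.extend(n.inputs)
        return out

    def to_dot(self) -> str:
        """GraphViz DOT text: ellipses for RVs (observed filled gray), boxes
        for deterministics, plate clusters labeled with batch sizes."""
        lines = ["digraph model {"]
        edges: list[tuple[str, str]] = []
        cluster = 0

        def emit(node_id, label, shape, filled, size):
            nonlocal cluster
            style = ', style="filled", fillcolor="lightgray"' if filled else ""
            decl = f'"{node_id}" [label="{label}", shape={shape}{style}];'
            if size is not None and size > 1:
                lines.append(f"  subgraph cluster_{cluster} {{")
                lines.append(f'    label="{size}"; labeljust="r"; labelloc="b";')
                lines.append(f"    {decl}")
                lines.append("  }")
                cluster += 1
            else:
                lines.append(f"  {decl}")

        for fv in self.free.values():
            shape_t = self.var_shape(fv)
            size = int(np.prod(shape_t)) if shape_t else None
            emit(fv.name, f"{fv.name}\\n~\\n{fv.rv.dist.family}", "ellipse",
                 False, size)
            for p in self._parents_of([fv.rv.dist.params[k]
                                       for k in fv.rv.dist.param_names]):
                edges.append((p, fv.name))
        for ov in self.observed.values():
            if ov.mask.any():
                emit(f"{ov.name}_observed",
                     f"{ov.name}_observed\\n~\\n{ov.rv.dist.family}",
                     "ellipse", True, ov.n_observed)
                edges.append((ov.name, f"{ov.name}_observed"))
            else:
                emit(ov.name, f"{ov.name}\\n~\\n{ov.rv.dist.family}",
                     "ellipse", True, int(ov.data.size) or None)
                for p in self._parents_of([ov.rv.dist.params[k]
                                           for k in ov.rv.dist.param_names]):
                    edges.append((p, ov.name))
        for name, node in self.deterministics.items():
            size = None
            dims = self.det_dims.get(name)
            if dims:
                size = int(np.prod([len(self.coords[d]) for d in dims]))
            emit(name, name, "box", False, size)
            for p in self._parents_of(list(node.inputs)):
                edges.append((p, name))
        # edges from parents into the combined/missing split
        for ov in self.observed.values():
            if ov.mask.any():
                emit(f"{ov.name}_missing",
                     f"{ov.name}_missing\\n~\\n{ov.rv.dist.family}",
                     "ellipse", False, ov.n_missing)
                edges.append((ov.name, f"{ov.name}_missing"))
                if ov.name not in self.deterministics:
                    emit(ov.name, ov.name, "box", False, int(ov.data.size))
                for p in self._parents_of([ov.rv.dist.params[k]
                                           for k in ov.rv.dist.param_names]):
                    edges.append((p, ov.name))
        for a, b in dict.fromkeys(edges):
            lines.append(f'  "{a}" -> "{b}";')
        lines.append("}")
        return "\n".join(lines)

    def __repr__(self):
        parts = [repr(fv.rv) for fv in self.free.values()]
        parts += [f"{ov.display_name} ~ {ov.rv.dist!r}"
                  for ov in self.observed.values()]
        return "ProbModel([" + ", ".join(parts) + "])"


def joint_logp(model: ProbModel, jacobian: bool = True) -> pt.TensorNode:
    """Module-level alias for :meth:`ProbModel.joint_logp`."""
    return model.joint_logp(jacobian=jacobian)
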