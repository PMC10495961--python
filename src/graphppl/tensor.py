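"""Symbolic tensor graphs with simplification and reverse-mode differentiation.

Expressions are built lazily as a DAG of :class:`TensorNode` objects and only
produce numbers when evaluated (``eval_node``) or compiled into a callable
(``compile_fn``).  The graph substrate is deliberately small: a single
double-precision interpreter backend, rank-only shape tracking (full shape
checking happens at evaluation time, following broadcasting rules), and a
fixed-point rewrite pass providing constant folding, inverse-pair
cancellation (``exp(log(u)) -> u``), numerically stable replacements
(``log(1+u) -> log1p(u)``, ``log(sum(exp(u))) -> logsumexp(u)``) and common
subexpression elimination.

Gradients are symbolic: :func:`grad` returns new graph nodes implementing
reverse-mode vector-Jacobian products, so gradients can themselves be
simplified, compiled and evaluated like any other expression.
"""

from __future__ import annotations

import itertools
import math
from typing import Any, Callable, Iterable, Sequence

import numpy as np
from scipy import special as sp_special

__all__ = [
    "TensorNode",
    "CompiledFunction",
    "make_input",
    "scalar",
    "vector",
    "matrix",
    "constant",
    "as_tensor",
    "apply_op",
    "simplify",
    "compile_fn",
    "eval_node",
    "grad",
    "graph_to_dot",
]

_COUNTER = itertools.count()

_RANKS = {"scalar": 0, "vector": 1, "matrix": 2}


class ShapeError(ValueError):
    """Operand shapes/ranks incompatible under broadcasting."""


class UnboundInputError(KeyError):
    """A reachable input node has no binding."""


# ---------------------------------------------------------------------------
# Node
# ---------------------------------------------------------------------------


class TensorNode:
    """One vertex of the expression DAG.

    kind is one of ``input`` (a placeholder bound at evaluation time),
    ``constant`` (carries a concrete value) or ``apply`` (an operation over
    operand nodes).  Identity is by object, not by name: two inputs named
    alike are distinct nodes.
    """

    __slots__ = ("kind", "op", "inputs", "rank", "name", "value", "params", "nid")

    def __init__(self, kind, op=None, inputs=(), rank=None, name=None,
                 value=None, params=None):
        self.kind = kind
        self.op = op
        self.inputs = tuple(inputs)
        self.rank = rank
        self.name = name
        self.value = value
        self.params = params or {}
        self.nid = next(_COUNTER)
        if kind == "input" and self.inputs:
            raise ValueError("input node cannot have operands")

    # -- ergonomic operator sugar ------------------------------------------
    def __add__(self, other):
        return apply_op("add", self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return apply_op("sub", self, other)

    def __rsub__(self, other):
        return apply_op("sub", other, self)

    def __mul__(self, other):
        return apply_op("mul", self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return apply_op("div", self, other)

    def __rtruediv__(self, other):
        return apply_op("div", other, self)

    def __pow__(self, other):
        return apply_op("pow", self, other)

    def __neg__(self):
        return apply_op("neg", self)

    def __lt__(self, other):
        return apply_op("lt", self, other)

    def __le__(self, other):
        return apply_op("le", self, other)

    def __gt__(self, other):
        return apply_op("gt", self, other)

    def __ge__(self, other):
        return apply_op("ge", self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def __hash__(self):
        return self.nid

    def __repr__(self):
        if self.kind == "input":
            return f"Input({self.name!r}, rank={self.rank})"
        if self.kind == "constant":
            return f"Constant({np.asarray(self.value)!r})"
        return f"Apply({self.op}, nid={self.nid}, name={self.name!r})"

    def eval(self, bindings=None, **kw):
        """Direct evaluation without persisting a compiled plan."""
        b = dict(bindings or {})
        b.update(kw)
        return eval_node(self, b)


def make_input(rank: str | int, name: str) -> TensorNode:
    """Create a free placeholder of declared rank (scalar/vector/matrix)."""
    if isinstance(rank, str):
        rank = _RANKS[rank]
    return TensorNode("input", rank=int(rank), name=name)


def scalar(name: str) -> TensorNode:
    return make_input(0, name)


def vector(name: str) -> TensorNode:
    return make_input(1, name)


def matrix(name: str) -> TensorNode:
    return make_input(2, name)


def constant(value, name=None) -> TensorNode:
    v = np.asarray(value)
    return TensorNode("constant", rank=v.ndim, name=name, value=v)


def as_tensor(x) -> TensorNode:
    if isinstance(x, TensorNode):
        return x
    return constant(x)


# ---------------------------------------------------------------------------
# Operation table
# ---------------------------------------------------------------------------

LOG_2PI = math.log(2.0 * math.pi)


def _sum_to(x, ref):
    """Sum ``x`` down to the broadcast shape of ``ref`` (gradient plumbing)."""
    x = np.asarray(x)
    shape = np.shape(ref)
    while x.ndim > len(shape):
        x = x.sum(axis=0)
    for i, (xs, ts) in enumerate(zip(x.shape, shape)):
        if ts == 1 and xs != 1:
            x = x.sum(axis=i, keepdims=True)
    if x.shape != tuple(shape):
        x = np.broadcast_to(x, shape)
    return x


def _bcast_like(g, ref, axis=None):
    g = np.asarray(g)
    ref = np.asarray(ref)
    if axis is not None:
        g = np.expand_dims(g, axis)
    return np.broadcast_to(g, ref.shape)


def _scatter_like(g, ref, idx):
    out = np.zeros_like(np.asarray(ref, dtype=float))
    np.add.at(out, idx, g)
    return out


def _put(base, vals, idx):
    out = np.array(base, dtype=np.result_type(base, vals), copy=True)
    out[idx] = vals
    return out


def _dot(a, b):
    return np.dot(a, b)


_EVAL: dict[str, Callable] = {
    "add": lambda a, b: a + b,
    "sub": lambda a, b: a - b,
    "mul": lambda a, b: a * b,
    "div": lambda a, b: a / b,
    "pow": lambda a, b: a ** b,
    "neg": lambda a: -a,
    "abs": np.abs,
    "sign": np.sign,
    "exp": np.exp,
    "expm1": np.expm1,
    "log": np.log,
    "log1p": np.log1p,
    "sqrt": np.sqrt,
    "sin": np.sin,
    "cos": np.cos,
    "erf": sp_special.erf,
    "erfc": sp_special.erfc,
    "logistic": sp_special.expit,
    "softplus": lambda a: np.logaddexp(0.0, a),
    "gammaln": sp_special.gammaln,
    "digamma": sp_special.psi,
    "polygamma1": lambda a: sp_special.polygamma(1, a),
    "log_ndtr": sp_special.log_ndtr,
    "gammaincc": sp_special.gammaincc,
    "floor": np.floor,
    "switch": lambda c, a, b: np.where(c, a, b),
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
    "eq": lambda a, b: a == b,
    "dot": _dot,
    "outer": np.outer,
    "transpose": np.transpose,
    "sum": None,  # handled with params
    "prod": None,
    "logsumexp": None,
    "take": None,
    "put": None,
    "sum_to": _sum_to,
    "bcast_like": None,
    "scatter_like": None,
    "zeros_like": lambda a: np.zeros_like(np.asarray(a, dtype=float)),
    "ones_like": lambda a: np.ones_like(np.asarray(a, dtype=float)),
}


def _eval_apply(op, vals, params):
    if op == "sum":
        return np.sum(vals[0], axis=params.get("axis"))
    if op == "prod":
        return np.prod(vals[0], axis=params.get("axis"))
    if op == "logsumexp":
        return sp_special.logsumexp(vals[0], axis=params.get("axis"))
    if op == "take":
        return np.asarray(vals[0])[params["idx"]]
    if op == "put":
        return _put(vals[0], vals[1], params["idx"])
    if op == "bcast_like":
        return _bcast_like(vals[0], vals[1], params.get("axis"))
    if op == "scatter_like":
        return _scatter_like(vals[0], vals[1], params["idx"])
    fn = _EVAL[op]
    return fn(*vals)


_ELEMWISE = {
    "add", "sub", "mul", "div", "pow", "neg", "abs", "sign", "exp", "expm1",
    "log", "log1p", "sqrt", "sin", "cos", "erf", "erfc", "logistic",
    "softplus", "gammaln", "digamma", "polygamma1", "log_ndtr", "floor",
    "switch", "lt", "le", "gt", "ge", "eq",
}


def _infer_rank(op, inputs, params):
    ranks = [i.rank for i in inputs]
    if op in _ELEMWISE:
        known = [r for r in ranks if r is not None]
        return max(known) if len(known) == len(ranks) else None
    if op in ("sum", "prod", "logsumexp"):
        axis = params.get("axis")
        r = ranks[0]
        if r is None:
            return None
        return 0 if axis is None else max(r - 1, 0)
    if op == "dot":
        ra, rb = ranks
        if ra is None or rb is None:
            return None
        return ra + rb - 2
    if op == "outer":
        return 2
    if op == "transpose":
        return ranks[0]
    if op == "take":
        idx = params["idx"]
        r = ranks[0]
        if r is None:
            return None
        if isinstance(idx, (int, np.integer)):
            return max(r - 1, 0)
        if isinstance(idx, slice):
            return r
        return r - 1 + np.asarray(idx).ndim
    if op in ("put", "sum_to", "zeros_like", "ones_like"):
        return ranks[0] if op != "sum_to" else inputs[1].rank
    if op in ("bcast_like", "scatter_like"):
        return inputs[1].rank
    return None


def apply_op(op: str, *operands, **params) -> TensorNode:
    """Build an apply node; operands are auto-wrapped as constants."""
    if op not in _EVAL:
        raise ValueError(f"unknown operation {op!r}")
    inputs = tuple(as_tensor(x) for x in operands)
    rank = _infer_rank(op, inputs, params)
    return TensorNode("apply", op=op, inputs=inputs, rank=rank, params=params)


# Named helpers ------------------------------------------------------------

def exp(x):
    return apply_op("exp", x)


def log(x):
    return apply_op("log", x)


def log1p(x):
    return apply_op("log1p", x)


def expm1(x):
    return apply_op("expm1", x)


def sqrt(x):
    return apply_op("sqrt", x)


def sin(x):
    return apply_op("sin", x)


def cos(x):
    return apply_op("cos", x)


def erf(x):
    return apply_op("erf", x)


def erfc(x):
    return apply_op("erfc", x)


def logistic(x):
    return apply_op("logistic", x)


def softplus(x):
    return apply_op("softplus", x)


def gammaln(x):
    return apply_op("gammaln", x)


def log_ndtr(x):
    return apply_op("log_ndtr", x)


def switch(cond, a, b):
    return apply_op("switch", cond, a, b)


def sum_(x, axis=None):
    return apply_op("sum", x, axis=axis)


def prod_(x, axis=None):
    return apply_op("prod", x, axis=axis)


def logsumexp(x, axis=None):
    return apply_op("logsumexp", x, axis=axis)


def dot(a, b):
    return apply_op("dot", a, b)


def take(x, idx):
    return apply_op("take", x, idx=idx)


def put(base, idx, vals):
    return apply_op("put", base, vals, idx=idx)


def zeros_like(x):
    return apply_op("zeros_like", x)


def eq(a, b):
    return apply_op("eq", a, b)


def abs_(x):
    return apply_op("abs", x)


def floor_(x):
    return apply_op("floor", x)


# ---------------------------------------------------------------------------
# Traversal
# ---------------------------------------------------------------------------


def topological_order(outputs: Sequence[TensorNode]) -> list[TensorNode]:
    """Iterative post-order DFS over the DAG (operands before dependents)."""
    order: list[TensorNode] = []
    seen: set[int] = set()
    stack: list[tuple[TensorNode, bool]] = [(o, False) for o in reversed(outputs)]
    while stack:
        node, expanded = stack.pop()
        if expanded:
            order.append(node)
            continue
        if node.nid in seen:
            continue
        seen.add(node.nid)
        stack.append((node, True))
        for child in reversed(node.inputs):
            if child.nid not in seen:
                stack.append((child, False))
    return order


def reachable_inputs(outputs: Sequence[TensorNode]) -> list[TensorNode]:
    return [n for n in topological_order(outputs) if n.kind == "input"]


def clone_replace(outputs: Sequence[TensorNode],
                  replacements: dict[TensorNode, TensorNode]) -> list[TensorNode]:
    """Rebuild the graph with the given node substitutions applied."""
    memo: dict[int, TensorNode] = {n.nid: r for n, r in replacements.items()}
    for node in topological_order(outputs):
        if node.nid in memo:
            continue
        if node.kind != "apply":
            memo[node.nid] = node
            continue
        new_inputs = tuple(memo[c.nid] for c in node.inputs)
        if all(a is b for a, b in zip(new_inputs, node.inputs)):
            memo[node.nid] = node
        else:
            memo[node.nid] = TensorNode("apply", op=node.op, inputs=new_inputs,
                                        rank=node.rank, name=node.name,
                                        params=node.params)
    return [memo[o.nid] for o in outputs]


# ---------------------------------------------------------------------------
# Simplification
# ---------------------------------------------------------------------------


def _params_key(params):
    items = []
    for k, v in sorted(params.items()):
        if isinstance(v, np.ndarray):
            items.append((k, ("arr", v.dtype.str, v.shape, v.tobytes())))
        elif isinstance(v, slice):
            items.append((k, ("slice", v.start, v.stop, v.step)))
        elif isinstance(v, (list, tuple)):
            items.append((k, ("seq", tuple(np.asarray(v).ravel().tolist()))))
        else:
            items.append((k, v))
    return tuple(items)


def _const_key(v):
    v = np.asarray(v)
    return ("const", v.dtype.str, v.shape, v.tobytes())


def _local_rewrite(op, inputs, params):
    """Return a replacement node, or None if no rule fires."""
    # constant folding
    if all(i.kind == "constant" for i in inputs):
        try:
            with np.errstate(all="ignore"):
                val = _eval_apply(op, [i.value for i in inputs], params)
            return constant(val)
        except Exception:
            return None
    a = inputs[0]
    if op == "exp" and a.kind == "apply" and a.op == "log":
        return a.inputs[0]
    if op == "log" and a.kind == "apply":
        if a.op == "exp":
            return a.inputs[0]
        if a.op == "add":
            u, v = a.inputs
            if u.kind == "constant" and np.ndim(u.value) == 0 and u.value == 1:
                return apply_op("log1p", v)
            if v.kind == "constant" and np.ndim(v.value) == 0 and v.value == 1:
                return apply_op("log1p", u)
        if a.op == "sum" and a.inputs[0].kind == "apply" \
                and a.inputs[0].op == "exp":
            return apply_op("logsumexp", a.inputs[0].inputs[0],
                            axis=a.params.get("axis"))
    return None


def simplify(*outputs: TensorNode, max_passes: int = 100) -> list[TensorNode]:
    """Rewrite the graph to a semantically equivalent, simpler one.

    Fixed-point iteration (pass cap ``max_passes``) over: constant folding,
    exp/log inverse-pair cancellation, log1p and log-sum-exp stabilization,
    and common-subexpression elimination by structural hashing.
    """
    outs = [as_tensor(o) for o in outputs]
    for _ in range(max_passes):
        cse: dict[Any, TensorNode] = {}
        memo: dict[int, TensorNode] = {}
        changed = False
        for node in topological_order(outs):
            if node.kind == "constant":
                key = _const_key(node.value)
                if key in cse:
                    memo[node.nid] = cse[key]
                    changed = changed or cse[key] is not node
                else:
                    cse[key] = node
                    memo[node.nid] = node
                continue
            if node.kind != "apply":
                memo[node.nid] = node
                continue
            new_inputs = tuple(memo[c.nid] for c in node.inputs)
            replaced = _local_rewrite(node.op, new_inputs, node.params)
            if replaced is not None:
                # the replacement subtree itself must be deduplicated
                if replaced.kind == "constant":
                    key = _const_key(replaced.value)
                    replaced = cse.setdefault(key, replaced)
                memo[node.nid] = replaced
                changed = True
                continue
            key = (node.op, tuple(c.nid for c in new_inputs),
                   _params_key(node.params))
            if key in cse:
                memo[node.nid] = cse[key]
                changed = True
                continue
            if all(a is b for a, b in zip(new_inputs, node.inputs)):
                new_node = node
            else:
                new_node = TensorNode("apply", op=node.op, inputs=new_inputs,
                                      rank=node.rank, name=node.name,
                                      params=node.params)
                changed = True
            cse[key] = new_node
            memo[node.nid] = new_node
        outs = [memo[o.nid] for o in outs]
        if not changed:
            break
    return outs


# ---------------------------------------------------------------------------
# Evaluation / compilation
# ---------------------------------------------------------------------------


def _resolve_bindings(inputs: Iterable[TensorNode], bindings: dict):
    """Map each input node to a numeric value from a node- or name-keyed dict."""
    inputs = list(inputs)
    out = {}
    by_name: dict[str, list[TensorNode]] = {}
    for node in inputs:
        by_name.setdefault(node.name, []).append(node)
    for node in inputs:
        if node in bindings:
            out[node.nid] = bindings[node]
        elif node.name is not None and node.name in bindings:
            if len(by_name[node.name]) > 1:
                raise UnboundInputError(
                    f"ambiguous binding: several inputs named {node.name!r}")
            out[node.nid] = bindings[node.name]
        else:
            raise UnboundInputError(
                f"missing binding for input {node.name or node.nid!r}")
    return out


def eval_node(node: TensorNode | Sequence[TensorNode], bindings=None):
    """Evaluate a node (or list of nodes) against name/node-keyed bindings."""
    single = isinstance(node, TensorNode)
    outputs = [node] if single else list(node)
    order = topological_order(outputs)
    bound = _resolve_bindings((n for n in order if n.kind == "input"),
                              bindings or {})
    vals: dict[int, Any] = {}
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for n in order:
            if n.kind == "input":
                vals[n.nid] = np.asarray(bound[n.nid])
            elif n.kind == "constant":
                vals[n.nid] = n.value
            elif n.kind == "apply":
                vals[n.nid] = _eval_apply(n.op, [vals[c.nid] for c in n.inputs],
                                          n.params)
            else:
                raise TypeError(
                    f"cannot evaluate node of kind {n.kind!r} "
                    f"({n.name or n.nid}); substitute it first")
    res = [np.asarray(vals[o.nid]) for o in outputs]
    return res[0] if single else res


class CompiledFunction:
    """A simplification + evaluation plan frozen into a callable.

    Pure: identical numeric inputs give bitwise-identical outputs.  Call
    positionally, by keyword (input names) or with a single dict.
    """

    def __init__(self, inputs: Sequence[TensorNode], outputs: Sequence[TensorNode]):
        self.inputs = list(inputs)
        raw_outputs = [as_tensor(o) for o in outputs]
        # keep declared inputs stable through simplification: inputs are
        # never rewritten, only apply nodes are.
        self.outputs = simplify(*raw_outputs)
        declared = {n.nid for n in self.inputs}
        for n in reachable_inputs(self.outputs):
            if n.nid not in declared:
                raise UnboundInputError(
                    f"output depends on undeclared input {n.name or n.nid!r}")
        order = topological_order(self.outputs)
        self._slot = {n.nid: i for i, n in enumerate(order)}
        self._n = len(order)
        self._base: list[Any] = [None] * self._n
        self._steps: list[tuple[int, str, tuple[int, ...], dict]] = []
        self._in_slots = []
        for n in order:
            if n.kind == "constant":
                self._base[self._slot[n.nid]] = n.value
            elif n.kind == "apply":
                self._steps.append((self._slot[n.nid], n.op,
                                    tuple(self._slot[c.nid] for c in n.inputs),
                                    n.params))
        for n in self.inputs:
            self._in_slots.append(self._slot.get(n.nid, -1))
        self._out_slots = [self._slot[o.nid] for o in self.outputs]
        self._single = len(self.outputs) == 1

    def __call__(self, *args, **kwargs):
        if len(args) == 1 and not kwargs and isinstance(args[0], dict):
            bound = _resolve_bindings(
                [n for n, s in zip(self.inputs, self._in_slots) if s >= 0],
                args[0])
            vals = list(self._base)
            for n, s in zip(self.inputs, self._in_slots):
                if s >= 0:
                    vals[s] = np.asarray(bound[n.nid])
        else:
            binding = {}
            for node, a in zip(self.inputs, args):
                binding[node] = a
            if kwargs:
                for k, v in kwargs.items():
                    binding[k] = v
            bound = _resolve_bindings(
                [n for n, s in zip(self.inputs, self._in_slots) if s >= 0],
                binding)
            vals = list(self._base)
            for n, s in zip(self.inputs, self._in_slots):
                if s >= 0:
                    vals[s] = np.asarray(bound[n.nid])
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            for slot, op, argslots, params in self._steps:
                vals[slot] = _eval_apply(op, [vals[i] for i in argslots], params)
        outs = [np.asarray(vals[s]) for s in self._out_slots]
        return outs[0] if self._single else outs


def compile_fn(inputs: Sequence[TensorNode],
               outputs: Sequence[TensorNode]) -> CompiledFunction:
    """Simplify and freeze an evaluation plan over the declared inputs."""
    return CompiledFunction(inputs, outputs)


# ---------------------------------------------------------------------------
# Reverse-mode differentiation
# ---------------------------------------------------------------------------

_C0 = None
_C1 = None


def _c0():
    global _C0
    if _C0 is None:
        _C0 = constant(0.0)
    return _C0


def _vjp(node: TensorNode, g: TensorNode) -> list[TensorNode | None]:
    """Gradient contributions of ``node``'s output w.r.t. each operand."""
    op = node.op
    ins = node.inputs
    if op == "add":
        return [apply_op("sum_to", g, ins[0]), apply_op("sum_to", g, ins[1])]
    if op == "sub":
        return [apply_op("sum_to", g, ins[0]),
                apply_op("sum_to", -g, ins[1])]
    if op == "neg":
        return [-g]
    if op == "mul":
        return [apply_op("sum_to", g * ins[1], ins[0]),
                apply_op("sum_to", g * ins[0], ins[1])]
    if op == "div":
        return [apply_op("sum_to", g / ins[1], ins[0]),
                apply_op("sum_to", -g * ins[0] / (ins[1] * ins[1]), ins[1])]
    if op == "pow":
        a, b = ins
        ga = apply_op("sum_to", g * b * a ** (b - constant(1.0)), a)
        if b.kind == "constant":
            return [ga, None]
        return [ga, apply_op("sum_to", g * node * log(a), b)]
    if op == "exp":
        return [g * node]
    if op == "expm1":
        return [g * exp(ins[0])]
    if op == "log":
        return [g / ins[0]]
    if op == "log1p":
        return [g / (constant(1.0) + ins[0])]
    if op == "sqrt":
        return [g / (constant(2.0) * node)]
    if op == "sin":
        return [g * cos(ins[0])]
    if op == "cos":
        return [-g * sin(ins[0])]
    if op == "erf":
        return [g * constant(2.0 / math.sqrt(math.pi)) * exp(-ins[0] * ins[0])]
    if op == "erfc":
        return [-g * constant(2.0 / math.sqrt(math.pi)) * exp(-ins[0] * ins[0])]
    if op == "logistic":
        return [g * node * (constant(1.0) - node)]
    if op == "softplus":
        return [g * logistic(ins[0])]
    if op == "gammaln":
        return [g * apply_op("digamma", ins[0])]
    if op == "digamma":
        return [g * apply_op("polygamma1", ins[0])]
    if op == "log_ndtr":
        z = ins[0]
        logpdf = -z * z * constant(0.5) - constant(0.5 * LOG_2PI)
        return [g * exp(logpdf - node)]
    if op == "abs":
        return [g * apply_op("sign", ins[0])]
    if op == "gammaincc":
        a, x = ins
        # d/dx of the regularized upper incomplete gamma Q(a, x)
        gx = -g * exp((a - constant(1.0)) * log(x) - x - gammaln(a))
        return [None, apply_op("sum_to", gx, x)]
    if op == "switch":
        c, a, b = ins
        z = _c0()
        return [None,
                apply_op("sum_to", switch(c, g, z), a),
                apply_op("sum_to", switch(c, z, g), b)]
    if op == "sum":
        return [apply_op("bcast_like", g, ins[0], axis=node.params.get("axis"))]
    if op == "prod":
        return [apply_op("bcast_like", g * node, ins[0],
                         axis=node.params.get("axis")) / ins[0]]
    if op == "logsumexp":
        axis = node.params.get("axis")
        gb = apply_op("bcast_like", g, ins[0], axis=axis)
        ob = apply_op("bcast_like", node, ins[0], axis=axis)
        return [gb * exp(ins[0] - ob)]
    if op == "dot":
        a, b = ins
        ra = a.rank if a.rank is not None else 1
        rb = b.rank if b.rank is not None else 1
        if ra == 1 and rb == 1:
            return [g * b, g * a]
        if ra == 2 and rb == 1:
            return [apply_op("outer", g, b), dot(apply_op("transpose", a), g)]
        if ra == 1 and rb == 2:
            return [dot(b, g), apply_op("outer", a, g)]
        if ra == 2 and rb == 2:
            return [dot(g, apply_op("transpose", b)),
                    dot(apply_op("transpose", a), g)]
        raise NotImplementedError("dot gradient for ranks > 2")
    if op == "outer":
        return [dot(g, ins[1]), dot(apply_op("transpose", g), ins[0])]
    if op == "transpose":
        return [apply_op("transpose", g)]
    if op == "take":
        return [apply_op("scatter_like", g, ins[0], idx=node.params["idx"])]
    if op == "put":
        idx = node.params["idx"]
        n_idx = len(np.atleast_1d(np.asarray(idx))) if not isinstance(idx, slice) else None
        if isinstance(idx, slice):
            raise NotImplementedError("put gradient with slice index")
        zero_fill = constant(np.zeros(np.shape(np.atleast_1d(np.asarray(idx)))))
        return [put(g, idx, zero_fill), take(g, idx)]
    if op in ("lt", "le", "gt", "ge", "eq", "sign", "floor",
              "zeros_like", "ones_like"):
        return [None] * len(ins)
    raise NotImplementedError(f"no gradient for op {op!r}")


def grad(objective: TensorNode, wrt: Sequence[TensorNode] | TensorNode):
    """Symbolic reverse-mode gradients of a scalar objective.

    Returns one node per ``wrt`` entry; inputs unreachable from the objective
    get a zero gradient of matching shape.
    """
    single = isinstance(wrt, TensorNode)
    wrt_list = [wrt] if single else list(wrt)
    if objective.rank is not None and objective.rank != 0:
        raise ValueError("grad objective must be scalar-valued")
    order = topological_order([objective])
    gmap: dict[int, TensorNode] = {objective.nid: constant(1.0)}
    for node in reversed(order):
        g = gmap.get(node.nid)
        if g is None or node.kind != "apply":
            continue
        contribs = _vjp(node, g)
        for child, c in zip(node.inputs, contribs):
            if c is None or child.kind == "constant":
                continue
            prev = gmap.get(child.nid)
            gmap[child.nid] = c if prev is None else prev + c
    grads = []
    for w in wrt_list:
        gw = gmap.get(w.nid)
        if gw is None:
            gw = zeros_like(w)
        else:
            gw = apply_op("sum_to", gw, w)
        grads.append(gw)
    return grads[0] if single else grads


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------


def _dot_label(node: TensorNode) -> str:
    if node.kind == "input":
        return node.name or f"in{node.nid}"
    if node.kind == "constant":
        v = np.asarray(node.value)
        return str(v) if v.ndim == 0 and v.size == 1 else f"const{v.shape}"
    return node.name or node.op


def graph_to_dot(outputs: Sequence[TensorNode] | TensorNode) -> str:
    """Export the expression DAG as GraphViz DOT text (debugging aid)."""
    if isinstance(outputs, TensorNode):
        outputs = [outputs]
    lines = ["digraph G {"]
    for node in topological_order(outputs):
        shape = {"input": "ellipse", "constant": "box"}.get(node.kind, "oval")
        lines.append(f'  n{node.nid} [label="{_dot_label(node)}", shape={shape}];')
        for child in node.inputs:
            lines.append(f"  n{child.nid} -> n{node.nid};")
    lines.append("}")
    return "\n".join(lines)
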