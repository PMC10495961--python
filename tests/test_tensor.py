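"""Graph construction, simplification, evaluation and autodiff."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphppl import tensor as pt


def test_make_input_ranks_and_identity():
    x = pt.make_input("scalar", "x")
    y = pt.make_input("vector", "y")
    assert x.rank == 0 and y.rank == 1
    assert x.kind == "input" and not x.inputs
    x2 = pt.make_input("scalar", "x")
    assert x2 is not x and x2.nid != x.nid  # identity by object, not name


def test_log_of_sum_evaluates_like_the_worked_example():
    x, y = pt.scalar("x"), pt.vector("y")
    z = pt.log(x + y)
    np.testing.assert_allclose(z.eval({"x": 0, "y": [1, np.e]}), [0.0, 1.0])
    f = pt.compile_fn([x, y], [z])
    np.testing.assert_allclose(f(x=0, y=[1, np.e]), [0.0, 1.0])


def test_eval_basic_ops():
    v = pt.vector("v")
    assert pt.dot(v, v).eval({"v": [1, 2, 3]}) == 14
    ones = pt.constant(np.ones((3, 4)))
    np.testing.assert_array_equal(pt.sum_(ones, axis=0).eval({}), [3, 3, 3, 3])
    c = pt.constant(7.5)
    assert c.eval({}) == 7.5
    cond = pt.constant(np.array([True, True]))
    a, b = pt.constant(np.array([1.0, 2.0])), pt.constant(np.array([9.0, 9.0]))
    np.testing.assert_array_equal(pt.switch(cond, a, b).eval({}), [1.0, 2.0])


def test_missing_binding_names_the_input():
    x = pt.scalar("alpha")
    with pytest.raises(KeyError, match="alpha"):
        (x + 1).eval({})


def test_compile_identity_and_undeclared_input_error():
    x = pt.scalar("x")
    f = pt.compile_fn([x], [x])
    assert f(x=3.5) == 3.5
    y = pt.scalar("y")
    with pytest.raises(KeyError, match="y"):
        pt.compile_fn([x], [x + y])


def test_compile_is_pure_bitwise():
    x = pt.vector("x")
    expr = pt.exp(pt.sin(x) * x) / (1 + x * x)
    f = pt.compile_fn([x], [expr])
    v = np.random.default_rng(0).normal(size=10)
    a, b = f(x=v), f(x=v)
    assert np.array_equal(a, b)


@pytest.mark.parametrize("builder,expected_op", [
    (lambda u: pt.exp(pt.log(u)), None),       # collapses to u itself
    (lambda u: pt.log(pt.exp(u)), None),
    (lambda u: pt.log(1.0 + u), "log1p"),
    (lambda u: pt.log(pt.sum_(pt.exp(u))), "logsumexp"),
])
def test_rewrite_rules_fire(builder, expected_op):
    u = pt.vector("u")
    out = pt.simplify(builder(u))[0]
    if expected_op is None:
        assert out is u
    else:
        assert out.op == expected_op


def test_constant_folding():
    out = pt.simplify(pt.log(pt.constant(1.0)))[0]
    assert out.kind == "constant" and out.value == 0.0


def test_cse_merges_duplicate_subexpressions():
    x = pt.vector("x")
    a = pt.exp(x) + pt.exp(x)
    out = pt.simplify(a)[0]
    assert out.inputs[0] is out.inputs[1]


def test_logsumexp_rewrite_is_numerically_stable():
    u = pt.vector("u")
    naive = pt.log(pt.sum_(pt.exp(u)))
    stable = pt.simplify(naive)[0]
    big = np.array([1000.0, 1000.0])
    assert np.isinf(naive.eval({"u": big}))  # overflow without the rewrite
    np.testing.assert_allclose(stable.eval({"u": big}),
                               1000 + np.log(2), rtol=1e-12)


@pytest.mark.parametrize("builder", [
    lambda u: pt.exp(pt.log(u * u + 0.5)),
    lambda u: pt.log(pt.exp(u - 2.0)),
    lambda u: pt.log(1.0 + u * u),
    lambda u: pt.log(pt.sum_(pt.exp(u))),
    lambda u: (pt.exp(u) + pt.exp(u)) * pt.sin(u),
])
def test_rewrites_preserve_semantics_on_random_inputs(builder):
    u = pt.vector("u")
    expr = builder(u)
    simplified = pt.simplify(expr)[0]
    rng = np.random.default_rng(42)
    for _ in range(100):
        v = rng.normal(size=5)
        # atol covers roundoff of the *unsimplified* form near zero, where
        # the stabilizing rewrites are strictly more accurate
        np.testing.assert_allclose(simplified.eval({"u": v}),
                                   expr.eval({"u": v}), rtol=1e-10, atol=1e-15)


def test_compiled_matches_unsimplified_interpreter_on_random_inputs():
    x, y = pt.scalar("x"), pt.vector("y")
    expr = pt.exp(pt.log(x * x + 1.0)) + pt.logistic(y) * pt.sqrt(y * y + x * x)
    f = pt.compile_fn([x, y], [expr])
    rng = np.random.default_rng(1)
    for _ in range(100):
        xv, yv = rng.normal(), rng.normal(size=4)
        np.testing.assert_allclose(f(x=xv, y=yv),
                                   expr.eval({"x": xv, "y": yv}), rtol=1e-12)


def _fd_grad(fn, x, h=1e-5):
    x = np.atleast_1d(np.asarray(x, dtype=float))
    g = np.zeros_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fn(xp) - fn(xm)) / (2 * h)
    return g


OP_CASES = [
    ("add", lambda v: pt.sum_(v + 2.0 * v), None),
    ("sub", lambda v: pt.sum_(v - v * v), None),
    ("mul_div", lambda v: pt.sum_(v * v / (1.0 + v * v)), None),
    ("pow", lambda v: pt.sum_((v * v + 1.0) ** 2.5), None),
    ("neg_exp", lambda v: pt.sum_(pt.exp(-v)), None),
    ("log", lambda v: pt.sum_(pt.log(v * v + 0.5)), None),
    ("log1p", lambda v: pt.sum_(pt.log1p(v * v)), None),
    ("expm1", lambda v: pt.sum_(pt.expm1(v)), None),
    ("sqrt", lambda v: pt.sum_(pt.sqrt(v * v + 1.0)), None),
    ("sin_cos", lambda v: pt.sum_(pt.sin(v) * pt.cos(v)), None),
    ("erf", lambda v: pt.sum_(pt.erf(v)), None),
    ("erfc", lambda v: pt.sum_(pt.erfc(v)), None),
    ("logistic", lambda v: pt.sum_(pt.logistic(v)), None),
    ("softplus", lambda v: pt.sum_(pt.softplus(v)), None),
    ("gammaln", lambda v: pt.sum_(pt.gammaln(v * v + 1.5)), None),
    ("log_ndtr", lambda v: pt.sum_(pt.log_ndtr(v)), None),
    ("gammaincc", lambda v: pt.sum_(pt.log(
        pt.apply_op("gammaincc", pt.constant(3.0), v * v + 1.0))), None),
    ("abs", lambda v: pt.sum_(pt.abs_(v) * v * v), None),
    ("switch", lambda v: pt.sum_(pt.switch(v > 0, v * v, pt.exp(v))), None),
    ("sum_axis", lambda v: pt.sum_(pt.sum_(pt.apply_op(
        "outer", v, v), axis=0) * v), None),
    ("prod", lambda v: pt.prod_(v * v + 1.0), None),
    ("logsumexp", lambda v: pt.logsumexp(v), None),
    ("dot_vv", lambda v: pt.dot(v, v), None),
    ("take", lambda v: pt.sum_(pt.take(v, np.array([0, 2, 2])) *
                               pt.constant(np.array([1.0, 2.0, 3.0]))), None),
    ("put", lambda v: pt.sum_(pt.put(pt.constant(np.zeros(6)),
                                     np.array([1, 4]),
                                     pt.take(v, np.array([0, 1]))) ** 2), None),
]


@pytest.mark.parametrize("name,builder,_", OP_CASES, ids=[c[0] for c in OP_CASES])
def test_gradients_match_finite_differences(name, builder, _):
    v = pt.vector("v")
    obj = builder(v)
    gnode = pt.grad(obj, v)
    rng = np.random.default_rng(7)
    for _ in range(5):
        x = rng.normal(size=4) + 0.1  # away from |x|=0 kinks
        sym = np.asarray(gnode.eval({"v": x}))
        num = _fd_grad(lambda xx: float(obj.eval({"v": xx})), x)
        np.testing.assert_allclose(sym, num, rtol=1e-4, atol=1e-6)


def test_grad_matrix_dot():
    m = pt.matrix("m")
    v = pt.vector("v")
    obj = pt.dot(v, pt.dot(m, v))
    gm, gv = pt.grad(obj, [m, v])
    rng = np.random.default_rng(3)
    M = rng.normal(size=(3, 3))
    V = rng.normal(size=3)
    np.testing.assert_allclose(gv.eval({"m": M, "v": V}), (M + M.T) @ V,
                               rtol=1e-10)
    np.testing.assert_allclose(gm.eval({"m": M, "v": V}), np.outer(V, V),
                               rtol=1e-10)


def test_grad_power_and_log_closed_forms():
    x = pt.scalar("x")
    assert pt.grad(x * x, x).eval({"x": 3.0}) == pytest.approx(6.0)
    assert pt.grad(pt.log(x), x).eval({"x": 2.0}) == pytest.approx(0.5)


def test_grad_unreachable_input_is_zero_of_matching_shape():
    x, y = pt.scalar("x"), pt.vector("y")
    g = pt.grad(x * x, y)
    np.testing.assert_array_equal(g.eval({"y": np.ones(3)}), np.zeros(3))


def test_grad_requires_scalar_objective():
    v = pt.vector("v")
    with pytest.raises(ValueError, match="scalar"):
        pt.grad(v * v, v)


def test_broadcast_gradient_sums_over_expanded_axes():
    a, v = pt.scalar("a"), pt.vector("v")
    obj = pt.sum_((a + v) * (a + v))
    ga = pt.grad(obj, a)
    val = np.array([1.0, 2.0, 3.0])
    assert ga.eval({"a": 1.0, "v": val}) == pytest.approx(2 * np.sum(1 + val))


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.floats(-3, 3), min_size=2, max_size=6))
def test_simplify_preserves_eval_property(vals):
    u = pt.vector("u")
    expr = pt.exp(pt.log(pt.sum_(pt.exp(u)))) + pt.log1p(pt.exp(u[0]))
    simp = pt.simplify(expr)[0]
    x = np.asarray(vals)
    np.testing.assert_allclose(simp.eval({"u": x}), expr.eval({"u": x}),
                               rtol=1e-10)


def test_dot_export_is_valid_dot_text():
    x, y = pt.scalar("x"), pt.vector("y")
    dot = pt.graph_to_dot(pt.log(x + y))
    assert dot.startswith("digraph") and dot.rstrip().endswith("}")
    assert dot.count("[") == dot.count("]")
    assert "->" in dot
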