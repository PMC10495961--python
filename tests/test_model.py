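"""Model container: registries, joint density, initial points, DOT export."""

import math
import re

import numpy as np
import pytest

import graphppl as gp
from graphppl import tensor as pt
from graphppl.distributions import (
    Normal, HalfNormal, Exponential, Uniform, Poisson, DiscreteUniform,
)
from graphppl.model import ProbModel


def test_regression_joint_logp_matches_transcript(regression_model):
    logp = regression_model.compile_logp()
    assert float(logp({"a": 0.5, "b_log__": 1.2})) == pytest.approx(
        -73.39055683, abs=1e-6)


def test_single_normal_joint_logp():
    m = ProbModel()
    m.add_free("x", Normal(0, 1))
    assert float(m.compile_logp()({"x": 0.0})) == pytest.approx(-0.9189385,
                                                                abs=1e-6)


def test_uniform_at_unconstrained_zero_includes_jacobian():
    # density 1 on (0,1) times logit-Jacobian 1/4 at u=0
    m = ProbModel()
    m.add_free("u", Uniform(0, 1))
    got = float(m.compile_logp()({"u_interval__": 0.0}))
    assert got == pytest.approx(math.log(0.25), abs=1e-9)
    # cross-check the Jacobian against the numeric derivative of the
    # backward map (change of variables)
    h = 1e-6
    t = m.free["u"].transform
    dxdu = (t.backward_value(h) - t.backward_value(-h)) / (2 * h)
    assert got == pytest.approx(math.log(float(dxdu)), abs=1e-6)


def test_joint_logp_additivity():
    """Removing an independent variable removes exactly its contribution."""
    m2 = ProbModel()
    m2.add_free("x", Normal(0, 1))
    m2.add_free("y", Exponential(2.0))
    both = float(m2.compile_logp()({"x": 0.7, "y_log__": -0.3}))
    m1 = ProbModel()
    m1.add_free("x", Normal(0, 1))
    only_x = float(m1.compile_logp()({"x": 0.7}))
    my = ProbModel()
    my.add_free("y", Exponential(2.0))
    only_y = float(my.compile_logp()({"y_log__": -0.3}))
    assert both == pytest.approx(only_x + only_y, rel=1e-12)


def test_accessors_and_reprs(regression_model):
    m = regression_model
    assert [rv.name for rv in m.basic_RVs] == ["a", "b", "obs"]
    assert [rv.name for rv in m.free_RVs] == ["a", "b"]
    assert repr(m.free_RVs[0]) == "a ~ Normal(0, 1)"
    assert repr(m.free_RVs[1]) == "b ~ HalfNormal(1)"
    assert repr(m.observed_RVs[0]) == "obs ~ Normal(mu, 1)"
    empty = ProbModel()
    assert empty.basic_RVs == [] and empty.free_RVs == []


def test_duplicate_name_and_unknown_dim_errors():
    m = ProbModel(coords={"city": ["a", "b", "c"]})
    m.add_free("x", Normal(0, 1), dims="city")
    with pytest.raises(ValueError, match="already in use"):
        m.add_free("x", Normal(0, 1))
    with pytest.raises(KeyError, match="country"):
        m.add_free("z", Normal(0, 1), dims="country")


def test_dims_and_shape_give_batched_variables():
    m = ProbModel(coords={"city": ["mumbai", "delhi", "pune"]})
    x = m.add_free("x", Normal(0, 1), dims="city")
    ip = m.initial_point()
    assert ip["x"].shape == (3,)
    m2 = ProbModel()
    m2.add_free("v", Normal(0, 1), shape=3)
    assert m2.initial_point()["v"].shape == (3,)


def test_initial_point_contract():
    m = ProbModel()
    m.add_free("x", Normal(0, 1))
    m.add_free("y", Normal(0, 1), initval=-3)
    point = m.initial_point()
    assert point["x"] == 0.0 and point["y"] == -3.0


def test_initval_forward_transformed():
    m = ProbModel()
    m.add_free("h", HalfNormal(1), initval=1.0)
    assert m.initial_point()["h_log__"] == pytest.approx(0.0)


def test_initval_outside_support_raises():
    m = ProbModel()
    m.add_free("h", HalfNormal(1), initval=-2.0)
    with pytest.raises(ValueError, match="h"):
        m.initial_point()


def test_jitter_stays_within_unit_band():
    m = ProbModel()
    m.add_free("x", Normal(0, 1))
    m.add_free("h", HalfNormal(1))
    base = m.initial_point()
    jit = m.initial_point(jitter=True, seed=4)
    for k in base:
        assert abs(jit[k] - base[k]) <= 1.0


def test_missing_value_split_on_coal_series(coal_model):
    ov = coal_model.observed["acc"]
    assert ov.n_observed == 109 and ov.n_missing == 2
    assert list(coal_model.free) == ["sp", "t_0", "t_1", "acc_missing"]
    # reconstruction: combined node reproduces data at observed indices
    point = coal_model.initial_point()
    combined = coal_model.observed_value_node(ov)
    vals = pt.eval_node(
        combined, {coal_model.free["acc_missing"].value_node:
                   point["acc_missing"]})
    np.testing.assert_array_equal(np.asarray(vals)[ov.obs_idx],
                                  ov.data[ov.obs_idx])


def test_no_missing_creates_no_latent():
    m = ProbModel()
    m.add_observed("y", Normal(0, 1), np.array([1.0, 2.0]))
    assert list(m.free) == []


def test_all_missing_is_fully_latent():
    m = ProbModel()
    lam = m.add_free("lam", Exponential(1))
    m.add_observed("y", Poisson(mu=lam), np.array([np.nan, np.nan, np.nan]))
    assert m.observed["y"].n_missing == 3
    # logp contribution reduces to the prior over the latent vector
    point = m.initial_point()
    lp = float(m.compile_logp()(point))
    assert np.isfinite(lp)


def test_deterministic_registered_and_named(regression_model):
    assert "mu" in regression_model.deterministics
    node = regression_model.deterministics["mu"]
    assert node.name == "mu"


def test_compile_dlogp_matches_finite_differences(regression_model):
    m = regression_model
    dlogp = m.compile_dlogp()
    logp = m.compile_logp()
    rng = np.random.default_rng(0)
    h = 1e-6
    for _ in range(20):
        point = {"a": rng.normal(), "b_log__": rng.normal()}
        g = dlogp(point)
        for k in point:
            p, q = dict(point), dict(point)
            p[k] += h
            q[k] -= h
            fd = (float(logp(p)) - float(logp(q))) / (2 * h)
            assert float(g[k]) == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_compiled_logp_pure_and_matches_eval(regression_model):
    m = regression_model
    f = m.compile_logp()
    point = {"a": 0.5, "b_log__": 1.2}
    assert float(f(point)) == float(f(point))
    direct = pt.eval_node(m.joint_logp(),
                          {fv.value_node: point[fv.transformed]
                           for fv in m.free.values()})
    assert float(f(point)) == float(direct)


def test_missing_key_in_point_raises_naming_it(regression_model):
    with pytest.raises(KeyError, match="b_log__"):
        regression_model.compile_logp()({"a": 0.5})


def test_observed_outside_support_gives_neg_inf():
    m = ProbModel()
    lam = m.add_free("lam", Exponential(1))
    m.add_observed("y", Poisson(mu=lam), np.array([-1.0]))
    assert float(m.compile_logp()({"lam_log__": 0.0})) == -np.inf


_NODE_RE = re.compile(r'^\s*"[^"]+" \[label=".*", shape=\w+.*\];$')
_EDGE_RE = re.compile(r'^\s*"[^"]+" -> "[^"]+";$')


def _check_dot_grammar(dot: str):
    lines = dot.splitlines()
    assert lines[0].startswith("digraph")
    assert lines[-1] == "}"
    depth = 0
    for ln in lines:
        depth += ln.count("{") - ln.count("}")
        assert depth >= 0
        if "->" in ln:
            assert _EDGE_RE.match(ln), ln
        elif "[label=" in ln:
            assert _NODE_RE.match(ln), ln
    assert depth == 0


def test_coal_dot_shows_observed_and_missing_plates(coal_model):
    dot = coal_model.to_dot()
    _check_dot_grammar(dot)
    assert 'label="2"' in dot
    assert 'label="109"' in dot
    assert "fillcolor" in dot           # observed part is filled
    assert "shape=box" in dot           # deterministic rate
    assert '"sp" -> "rate"' in dot


def test_single_rv_dot_has_no_cluster():
    m = ProbModel()
    m.add_free("x", Normal(0, 1))
    dot = m.to_dot()
    _check_dot_grammar(dot)
    assert "cluster" not in dot
    assert "shape=ellipse" in dot
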