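"""Trace container, summaries, diagnostics and persistence."""

import math

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, settings, strategies as st

import graphppl as gp
from graphppl.trace import (
    TraceStore, dataset_from_arrays, summarize, hdi, rhat, ess,
    save_trace, load_trace, select, SUMMARY_COLUMNS,
)


def _iid_trace(seed=0, chains=4, draws=1000):
    rng = np.random.default_rng(seed)
    ds = dataset_from_arrays({"x": rng.normal(size=(chains, draws))}, {}, {})
    return TraceStore({"posterior": ds})


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


def test_group_names_are_restricted():
    ds = dataset_from_arrays({"x": np.zeros((1, 2))}, {}, {})
    with pytest.raises(ValueError, match="unknown trace group"):
        TraceStore({"not_a_group": ds})


def test_inconsistent_chain_draw_sizes_rejected():
    ds = xr.Dataset({
        "a": (("chain", "draw"), np.zeros((2, 10))),
        "b": (("chain", "draw2"), np.zeros((2, 5))),
    })
    with pytest.raises(ValueError, match="inconsistent"):
        TraceStore({"posterior": ds})


def test_extend_merges_groups():
    t1 = _iid_trace()
    ds = dataset_from_arrays({"y": np.ones((4, 1000))}, {}, {})
    t2 = TraceStore({"prior": ds})
    t1.extend(t2)
    assert "prior" in t1.groups and "posterior" in t1.groups


def test_select_by_label_and_errors():
    coords = {"tree": np.array(["pine", "oak"])}
    ds = dataset_from_arrays({"frac": np.zeros((2, 5, 2))},
                             {"frac": ("tree",)}, coords)
    tr = TraceStore({"posterior": ds})
    da = select(tr, "posterior", "frac", tree="pine")
    assert da.shape == (2, 5)
    with pytest.raises(KeyError, match="oak"):
        select(tr, "posterior", "frac", tree="birch")
    with pytest.raises(KeyError, match="choices"):
        select(tr, "posterior", "nope")


def test_label_slices_partition_the_array():
    coords = {"tree": np.array(["pine", "oak", "fir"])}
    vals = np.arange(2 * 4 * 3, dtype=float).reshape(2, 4, 3)
    ds = dataset_from_arrays({"frac": vals}, {"frac": ("tree",)}, coords)
    tr = TraceStore({"posterior": ds})
    parts = [select(tr, "posterior", "frac", tree=t).values
             for t in coords["tree"]]
    np.testing.assert_array_equal(np.stack(parts, axis=-1), vals)


# ---------------------------------------------------------------------------
# hdi
# ---------------------------------------------------------------------------


def test_hdi_flat_density_width():
    u = np.random.default_rng(0).uniform(size=20000)
    lo, hi = hdi(u, 0.94)
    assert hi - lo == pytest.approx(0.94, abs=0.01)


def test_hdi_exponential_pinned_at_zero():
    x = np.random.default_rng(1).exponential(size=20000)
    lo, hi = hdi(x, 0.94)
    assert lo == pytest.approx(0.0, abs=0.01)
    assert hi == pytest.approx(-math.log(1 - 0.94), abs=0.1)


def test_hdi_validates_prob_and_sample_count():
    with pytest.raises(ValueError):
        hdi([1.0, 2.0], prob=1.5)
    with pytest.raises(ValueError):
        hdi([1.0], prob=0.9)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(-100, 100), min_size=5, max_size=60, unique=True),
       st.integers(0, 1000))
def test_hdi_permutation_invariant_and_monotone(vals, perm_seed):
    x = np.asarray(vals)
    shuffled = np.random.default_rng(perm_seed).permutation(x)
    assert hdi(x, 0.9) == hdi(shuffled, 0.9)
    lo1, hi1 = hdi(x, 0.5)
    lo2, hi2 = hdi(x, 0.9)
    assert (hi2 - lo2) >= (hi1 - lo1)


# ---------------------------------------------------------------------------
# rhat / ess
# ---------------------------------------------------------------------------


def test_rhat_flags_shifted_chains():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(4, 500))
    x[0] += 10
    assert rhat(x) > 1.1


def test_rhat_near_one_for_iid():
    x = np.random.default_rng(0).normal(size=(4, 1000))
    assert 0.99 <= rhat(x) <= 1.01


def test_rhat_constant_chains_is_nan():
    assert np.isnan(rhat(np.ones((4, 100))))


def test_rhat_single_chain_warns_nan():
    with pytest.warns(UserWarning):
        assert np.isnan(rhat(np.zeros((1, 100))))


def test_ess_of_ar1_matches_analytic_autocorrelation_time():
    rho = 0.9
    rng = np.random.default_rng(8)
    n, chains = 5000, 4
    x = np.zeros((chains, n))
    for c in range(chains):
        e = rng.normal(size=n)
        for t in range(1, n):
            x[c, t] = rho * x[c, t - 1] + e[t] * math.sqrt(1 - rho ** 2)
    got = ess(x, "mean")
    want = chains * n * (1 - rho) / (1 + rho)
    assert abs(got - want) / want < 0.3


def test_diagnostics_match_arviz_oracle():
    az = pytest.importorskip("arviz")
    x = np.random.default_rng(12).normal(size=(4, 800))
    idata = az.convert_to_inference_data(x)
    assert rhat(x) == pytest.approx(float(az.rhat(idata).x), rel=1e-6)
    assert ess(x, "bulk") == pytest.approx(float(az.ess(idata).x), rel=1e-6)
    assert ess(x, "tail") == pytest.approx(
        float(az.ess(idata, method="tail").x), rel=0.05)


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------


def test_summary_columns_match_reporting_convention():
    df = summarize(_iid_trace())
    assert list(df.columns) == SUMMARY_COLUMNS


def test_summary_of_injected_iid_draws():
    df = summarize(_iid_trace(seed=5))
    row = df.loc["x"]
    assert abs(row["mean"]) < 0.05
    assert row["sd"] == pytest.approx(1.0, abs=0.05)
    assert 0.99 <= row["r_hat"] <= 1.01
    assert abs(row["ess_bulk"] - 4000) / 4000 < 0.3
    assert row["hdi_3%"] < row["hdi_97%"]


def test_summary_constant_chain_degenerates_gracefully():
    ds = dataset_from_arrays({"c": np.full((2, 50), 3.14)}, {}, {})
    df = summarize(TraceStore({"posterior": ds}))
    row = df.loc["c"]
    assert row["sd"] == pytest.approx(0.0, abs=1e-12)
    assert row["hdi_3%"] == pytest.approx(row["hdi_97%"])
    assert row["hdi_3%"] == pytest.approx(3.14)
    assert np.isnan(row["r_hat"])


def test_summary_unknown_variable_raises():
    with pytest.raises(KeyError, match="nope"):
        summarize(_iid_trace(), var_names=["nope"])


def test_summary_labels_vector_coordinates():
    coords = {"tree": np.array(["pine", "oak"])}
    ds = dataset_from_arrays(
        {"frac": np.random.default_rng(0).normal(size=(2, 100, 2))},
        {"frac": ("tree",)}, coords)
    df = summarize(TraceStore({"posterior": ds}))
    assert list(df.index) == ["frac[pine]", "frac[oak]"]


def test_summary_on_long_conjugate_run_matches_analytic(conjugate_y):
    from conftest import make_conjugate_model, conjugate_posterior
    m = make_conjugate_model(conjugate_y)
    tr = gp.sample(m, draws=1500, tune=500, chains=4, seed=21)
    df = summarize(tr, var_names=["theta"])
    mean_true, sd_true = conjugate_posterior(conjugate_y)
    row = df.loc["theta"]
    assert abs(row["mean"] - mean_true) < 3 * row["mcse_mean"]
    assert row["sd"] == pytest.approx(sd_true, rel=0.1)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def test_save_load_round_trip_is_bitwise(tmp_path, coal_model):
    tr = gp.sample(coal_model, draws=50, tune=50, chains=2, seed=1)
    gp.compute_log_likelihood(coal_model, tr)
    path = str(tmp_path / "trace.zip")
    save_trace(tr, path)
    back = load_trace(path)
    assert set(back.groups) == set(tr.groups)
    for g in tr.groups:
        for v in tr.groups[g].data_vars:
            assert np.array_equal(back.groups[g][v].values,
                                  tr.groups[g][v].values, equal_nan=True)
    np.testing.assert_array_equal(back.posterior["rate"].coords["year"].values,
                                  np.arange(1851, 1962))


def test_load_truncated_file_raises_cleanly(tmp_path):
    p = tmp_path / "broken.zip"
    tr = _iid_trace()
    save_trace(tr, str(p))
    data = p.read_bytes()
    p.write_bytes(data[: len(data) // 2])
    with pytest.raises(ValueError, match="cannot read"):
        load_trace(str(p))


def test_load_rejects_version_mismatch(tmp_path):
    import json
    import zipfile
    p = tmp_path / "old.zip"
    with zipfile.ZipFile(p, "w") as zf:
        zf.writestr("meta.json", json.dumps({"version": 999, "groups": {}}))
    with pytest.raises(ValueError, match="version"):
        load_trace(str(p))
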