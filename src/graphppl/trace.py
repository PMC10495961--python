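"""Labeled trace container and posterior summary statistics.

A :class:`TraceStore` holds named groups (posterior, prior,
prior_predictive, posterior_predictive, sample_stats, log_likelihood,
observed_data) of :class:`xarray.Dataset` objects whose variables carry
leading ``(chain, draw)`` dimensions followed by model-declared dimensions
with coordinate labels.

Summary statistics follow the usual posterior-table conventions: mean, sd,
highest-density interval (94% by default, computed as the shortest interval
containing the requested fraction of sorted draws), Monte-Carlo standard
errors, rank-normalized split-R-hat and rank-normalized bulk/tail effective
sample sizes with Geyer's initial positive/monotone truncation.
"""

from __future__ import annotations

import io
import json
import zipfile

import numpy as np
import pandas as pd
import xarray as xr
from scipy import special as sp_special

__all__ = [
    "TraceStore", "summarize", "hdi", "rhat", "ess",
    "save_trace", "load_trace", "select",
]

GROUP_NAMES = (
    "posterior", "prior", "prior_predictive", "posterior_predictive",
    "sample_stats", "log_likelihood", "observed_data",
)

_FORMAT_VERSION = 1


class TraceStore:
    """Grouped, labeled draw arrays with run metadata."""

    def __init__(self, groups: dict[str, xr.Dataset] | None = None,
                 metadata: dict | None = None):
        self.groups: dict[str, xr.Dataset] = {}
        self.metadata: dict = dict(metadata or {})
        for name, ds in (groups or {}).items():
            self.add_group(name, ds)

    def add_group(self, name: str, dataset: xr.Dataset) -> None:
        if name not in GROUP_NAMES:
            raise ValueError(f"unknown trace group {name!r}; "
                             f"expected one of {GROUP_NAMES}")
        if not isinstance(dataset, xr.Dataset):
            raise TypeError("group payload must be an xarray.Dataset")
        if name != "observed_data":
            lens = {v: (dataset[v].sizes.get("chain"),
                        dataset[v].sizes.get("draw"))
                    for v in dataset.data_vars}
            if len(set(lens.values())) > 1:
                raise ValueError(f"inconsistent (chain, draw) sizes in {name}: "
                                 f"{lens}")
        self.groups[name] = dataset

    def extend(self, other: "TraceStore") -> "TraceStore":
        for name, ds in other.groups.items():
            self.groups[name] = ds
        self.metadata.update(other.metadata)
        return self

    def __getattr__(self, name):
        groups = object.__getattribute__(self, "groups")
        if name in groups:
            return groups[name]
        raise AttributeError(name)

    def __contains__(self, name):
        return name in self.groups

    def __repr__(self):
        parts = []
        for name, ds in self.groups.items():
            parts.append(f"{name}: {list(ds.data_vars)}")
        return "TraceStore(" + "; ".join(parts) + ")"


def dataset_from_arrays(arrays: dict[str, np.ndarray],
                        dims: dict[str, tuple[str, ...]],
                        coords: dict[str, np.ndarray] | None = None,
                        leading=("chain", "draw")) -> xr.Dataset:
    """Assemble a Dataset; each array gets leading (chain, draw) dims."""
    coords = coords or {}
    data_vars = {}
    used_coords = {}
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        var_dims = list(leading) + list(dims.get(name) or ())
        # pad unnamed trailing dims
        extra = arr.ndim - len(var_dims)
        for i in range(extra):
            var_dims.append(f"{name}_dim_{i}")
        data_vars[name] = (tuple(var_dims), arr)
        for d in var_dims:
            if d in coords:
                used_coords[d] = np.asarray(coords[d])
    if leading and data_vars:
        shape0 = next(iter(data_vars.values()))[1].shape
        used_coords.setdefault("chain", np.arange(shape0[0]))
        used_coords.setdefault("draw", np.arange(shape0[1]))
    return xr.Dataset(data_vars, coords=used_coords)


def select(trace: TraceStore, group: str, var: str, **labels) -> xr.DataArray:
    """Label-based selection; unknown labels raise with the valid choices."""
    if group not in trace.groups:
        raise KeyError(f"trace has no group {group!r}")
    ds = trace.groups[group]
    if var not in ds:
        raise KeyError(f"group {group!r} has no variable {var!r}; "
                       f"choices: {list(ds.data_vars)}")
    da = ds[var]
    for dim, label in labels.items():
        valid = da.coords[dim].values if dim in da.coords else None
        if valid is not None and label not in valid:
            raise KeyError(f"label {label!r} not found in dim {dim!r}; "
                           f"valid labels: {list(valid)}")
    return da.sel(**labels)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


def hdi(samples, prob: float = 0.94) -> tuple[float, float]:
    """Shortest interval containing ``ceil(prob * n)`` sorted samples."""
    if not 0 < prob < 1:
        raise ValueError("prob must be in (0, 1)")
    x = np.sort(np.ravel(np.asarray(samples, dtype=float)))
    x = x[np.isfinite(x)]
    n = x.size
    if n < 2:
        raise ValueError("hdi needs at least 2 finite samples")
    m = int(np.ceil(prob * n))
    m = min(m, n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def _split_chains(x: np.ndarray) -> np.ndarray:
    """(chains, draws) -> (2*chains, draws//2), dropping an odd last draw."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m, n = x.shape
    half = n // 2
    return np.vstack([x[:, :half], x[:, n - half:]])


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    from scipy.stats import rankdata
    shape = x.shape
    flat = x.ravel()
    ranks = rankdata(flat, method="average")
    # fractional offset (Blom) before the probit map
    u = (ranks - 3.0 / 8.0) / (flat.size + 1.0 / 4.0)
    return sp_special.ndtri(u).reshape(shape)


def _rhat_base(x: np.ndarray) -> float:
    x = np.atleast_2d(x)
    m, n = x.shape
    if m < 2 or n < 2:
        return np.nan
    chain_means = x.mean(axis=1)
    chain_vars = x.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = n * chain_means.var(ddof=1)
    if w == 0:
        return np.nan
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def rhat(x) -> float:
    """Rank-normalized split R-hat over a (chains, draws) array."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] < 2 or x.shape[1] < 4:
        import warnings
        warnings.warn("rhat needs >= 2 chains and >= 4 draws; returning NaN")
        return np.nan
    if np.allclose(x, x.ravel()[0]):
        return np.nan
    z = _rank_normalize(_split_chains(x))
    folded = _rank_normalize(_split_chains(np.abs(x - np.median(x))))
    return float(np.nanmax([_rhat_base(z), _rhat_base(folded)]))


def _ess_base(x: np.ndarray) -> float:
    """ESS of a (chains, draws) array via Geyer initial monotone sequence."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    m, n = x.shape
    if n < 4:
        return np.nan
    if np.allclose(x, x.ravel()[0]):
        return np.nan
    # per-chain autocovariance by FFT
    xc = x - x.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), size, axis=1)[:, :n].real / n
    chain_var = acov[:, 0] * n / (n - 1.0)
    w = chain_var.mean()
    mean_acov = acov.mean(axis=0)
    if m > 1:
        var_plus = w * (n - 1.0) / n + x.mean(axis=1).var(ddof=1)
    else:
        var_plus = w * (n - 1.0) / n
    if var_plus == 0:
        return np.nan
    rho = 1.0 - (w - mean_acov) / var_plus
    rho[0] = 1.0
    # Geyer initial positive + monotone sequence over pairs
    # (rho_{2k} + rho_{2k+1}); tau = -1 + 2 * sum of retained pairs
    tau = -1.0
    t = 0
    prev_pair = np.inf
    while t + 1 < n:
        p = rho[t] + rho[t + 1]
        if p <= 0:
            break
        p = min(p, prev_pair)
        prev_pair = p
        tau += 2.0 * p
        t += 2
    tau = max(tau, 1.0 / np.log10(m * n + 1.0))
    ess_val = m * n / tau
    return float(min(ess_val, m * n * np.log10(m * n)))


def ess(x, kind: str = "bulk") -> float:
    """Rank-normalized effective sample size (bulk) or tail ESS.

    Tail ESS is the minimum of the ESS of the 5% and 95% quantile
    exceedance indicators.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if kind == "bulk":
        return _ess_base(_rank_normalize(_split_chains(x)))
    if kind == "tail":
        out = []
        for q in (0.05, 0.95):
            thr = np.quantile(x, q)
            ind = (x <= thr).astype(float)
            out.append(_ess_base(_rank_normalize(_split_chains(ind))))
        if np.all(np.isnan(out)):
            return np.nan
        return float(np.nanmin(out))
    if kind == "mean":
        return _ess_base(_split_chains(x))
    raise ValueError("kind must be 'bulk', 'tail' or 'mean'")


def _mcse_sd(sd: float, ess_val: float) -> float:
    if not np.isfinite(ess_val) or ess_val <= 1:
        return np.nan
    # delta-method approximation for the MC error of a standard deviation
    fac = np.exp(1.0) * (1.0 - 1.0 / ess_val) ** (ess_val - 1.0) - 1.0
    return float(sd * np.sqrt(max(fac, 0.0)))


SUMMARY_COLUMNS = ["mean", "sd", "hdi_3%", "hdi_97%", "mcse_mean", "mcse_sd",
                   "ess_bulk", "ess_tail", "r_hat"]


def summarize(trace: TraceStore, var_names=None, hdi_prob: float = 0.94,
              group: str = "posterior") -> pd.DataFrame:
    """One summary row per scalar coordinate of each posterior variable."""
    if group not in trace.groups:
        raise ValueError(f"trace has no {group!r} group")
    ds = trace.groups[group]
    if var_names is None:
        var_names = list(ds.data_vars)
    rows = {}
    lo_lab = f"hdi_{100 * (1 - hdi_prob) / 2:g}%"
    hi_lab = f"hdi_{100 * (1 - (1 - hdi_prob) / 2):g}%"
    cols = ["mean", "sd", lo_lab, hi_lab, "mcse_mean", "mcse_sd",
            "ess_bulk", "ess_tail", "r_hat"]
    for name in var_names:
        if name not in ds:
            raise KeyError(f"variable {name!r} not in {group}; "
                           f"choices: {list(ds.data_vars)}")
        da = ds[name]
        extra_dims = [d for d in da.dims if d not in ("chain", "draw")]
        if extra_dims:
            stacked = da.stack(__scalar__=extra_dims)
            labels = stacked.coords["__scalar__"].values
            for i, lab in enumerate(labels):
                lab_txt = ", ".join(str(v) for v in np.atleast_1d(lab))
                rows[f"{name}[{lab_txt}]"] = _summary_row(
                    stacked.isel(__scalar__=i).values, hdi_prob)
        else:
            rows[name] = _summary_row(da.values, hdi_prob)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = cols
    return df


def _summary_row(x: np.ndarray, hdi_prob: float) -> list[float]:
    x = np.atleast_2d(x)
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    lo, hi = hdi(x, hdi_prob) if sd > 0 else (mean, mean)
    e_bulk = ess(x, "bulk") if sd > 0 else np.nan
    e_tail = ess(x, "tail") if sd > 0 else np.nan
    r = rhat(x)
    mcse_mean = sd / np.sqrt(e_bulk) if np.isfinite(e_bulk) and e_bulk > 0 \
        else np.nan
    return [mean, sd, lo, hi, mcse_mean, _mcse_sd(sd, e_bulk), e_bulk,
            e_tail, r]


# ---------------------------------------------------------------------------
# Persistence: JSON metadata + npz arrays in one zip container
# ---------------------------------------------------------------------------


def save_trace(trace: TraceStore, path: str) -> None:
    """Lossless single-file round trip of groups, dims, coords, metadata."""
    meta = {"version": _FORMAT_VERSION, "metadata": trace.metadata,
            "groups": {}}
    arrays = {}
    for gname, ds in trace.groups.items():
        gmeta = {"vars": {}, "coords": {}}
        for vname, da in ds.data_vars.items():
            key = f"{gname}::{vname}"
            arrays[key] = np.asarray(da.values)
            gmeta["vars"][vname] = {"dims": list(da.dims)}
        for cname, cvals in ds.coords.items():
            key = f"{gname}::coord::{cname}"
            arrays[key] = np.asarray(cvals.values)
            gmeta["coords"][cname] = True
        meta["groups"][gname] = gmeta
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta))
        for key, arr in arrays.items():
            buf = io.BytesIO()
            np.save(buf, arr, allow_pickle=False)
            zf.writestr(key + ".npy", buf.getvalue())


def load_trace(path: str) -> TraceStore:
    try:
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("version") != _FORMAT_VERSION:
                raise ValueError(
                    f"trace file version {meta.get('version')} not supported "
                    f"(expected {_FORMAT_VERSION})")
            groups = {}
            for gname, gmeta in meta["groups"].items():
                data_vars = {}
                coords = {}
                for vname, vmeta in gmeta["vars"].items():
                    buf = io.BytesIO(zf.read(f"{gname}::{vname}.npy"))
                    data_vars[vname] = (tuple(vmeta["dims"]),
                                        np.load(buf, allow_pickle=False))
                for cname in gmeta["coords"]:
                    buf = io.BytesIO(zf.read(f"{gname}::coord::{cname}.npy"))
                    coords[cname] = np.load(buf, allow_pickle=False)
                groups[gname] = xr.Dataset(data_vars, coords=coords)
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read trace file {path!r}: {exc}") from exc
    return TraceStore(groups, metadata=meta.get("metadata"))
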