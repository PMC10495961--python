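"""Embedded datasets, the case-study model builders, and synthetic generators.

Three worked models exercise the whole stack:

* the change-point Poisson model for the 1851-1961 UK coal-mining disaster
  series (111 yearly counts, two of them missing): a discrete uniform
  switch-point, Exponential(1) rates before/after, and a Poisson likelihood
  whose rate switches at the unknown year;
* the linear-regression model (Normal intercept, HalfNormal slope,
  unit-noise Normal likelihood) on the seeded fixture dataset of 50 x-values
  evenly spaced on [-1, 1] with y = 3x + standard-normal noise drawn from
  the PCG64 default generator seeded with 0;
* a hierarchical non-centered Bradley-Terry ranking model (win probability
  is the logistic of the latent skill difference) and a marginalized
  Dirichlet-multinomial model for forest x tree-species count tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import tensor as pt
from .distributions import (
    Normal, HalfNormal, Exponential, Poisson, DiscreteUniform, Bernoulli,
    Dirichlet, LogNormal, DirichletMultinomial,
)
from .model import ProbModel

__all__ = [
    "coal_disasters", "regression_fixture",
    "build_coal_model", "build_regression_model", "build_bradley_terry",
    "build_dirichlet_multinomial",
    "BradleyTerryConfig", "ForestCountsConfig",
    "simulate_bradley_terry", "simulate_forest_counts",
]


# ---------------------------------------------------------------------------
# Embedded / seeded datasets
# ---------------------------------------------------------------------------


def coal_disasters() -> pd.Series:
    """Yearly UK coal-mining disaster counts, 1851-1961 (NaN = missing)."""
    with resources.files("graphppl").joinpath("data/coal_disasters.csv"
                                              ).open() as fh:
        df = pd.read_csv(fh)
    return pd.Series(df["count"].to_numpy(dtype=float),
                     index=df["year"].to_numpy(dtype=int), name="disasters")


def regression_fixture(n: int = 50, slope: float = 3.0, seed: int = 0):
    """The seeded regression dataset: x on [-1, 1], y = slope*x + N(0, 1).

    The noise stream is the PCG64 default generator; with the default
    arguments this reproduces the transcript values of the worked example
    exactly (joint logp -73.39055683 at {a: 0.5, b_log__: 1.2}).
    """
    rng = np.random.default_rng(seed=seed)
    x = np.linspace(-1, 1, n)
    y = rng.normal(x * slope, 1.0)
    return x, y


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------


def build_regression_model(x=None, y=None) -> ProbModel:
    """Normal intercept, HalfNormal slope, unit-noise Normal likelihood."""
    if x is None or y is None:
        x, y = regression_fixture()
    model = ProbModel()
    a = model.add_free("a", Normal(0, 1))
    b = model.add_free("b", HalfNormal(1))
    mu = model.add_deterministic("mu", a + b * pt.constant(np.asarray(x)))
    model.add_observed("obs", Normal(mu=mu, sigma=1), np.asarray(y))
    return model


def build_coal_model(data: pd.Series | None = None) -> ProbModel:
    """Change-point Poisson model on the coal-mining disaster series."""
    if data is None:
        data = coal_disasters()
    years = np.asarray(data.index, dtype=int)
    model = ProbModel(coords={"year": years})
    sp = model.add_free("sp", DiscreteUniform(int(years.min()),
                                              int(years.max())))
    t0 = model.add_free("t_0", Exponential(1))
    t1 = model.add_free("t_1", Exponential(1))
    model.add_deterministic(
        "rate", pt.switch(sp < pt.constant(years), t0, t1), dims="year")
    model.add_observed("acc", Poisson(mu=model.deterministics["rate"]),
                       data.to_numpy(dtype=float), dims="year")
    return model


def build_bradley_terry(winner_ids, loser_ids, n_players: int,
                        player_names=None) -> ProbModel:
    """Hierarchical non-centered Bradley-Terry ranking model.

    sd ~ HalfNormal(1); skill_raw_i ~ Normal(0, 1); skill = skill_raw * sd;
    each listed match is a win of ``winner_ids[k]`` over ``loser_ids[k]``
    with probability logistic(skill_w - skill_l).
    """
    winner_ids = np.asarray(winner_ids, dtype=int)
    loser_ids = np.asarray(loser_ids, dtype=int)
    if winner_ids.shape != loser_ids.shape:
        raise ValueError("winner_ids and loser_ids must have the same shape")
    if player_names is None:
        player_names = np.array([f"p{i}" for i in range(n_players)])
    model = ProbModel(coords={"player": np.asarray(player_names)})
    sd = model.add_free("sd", HalfNormal(1.0))
    skill_raw = model.add_free("skill_raw", Normal(0.0, 1.0), dims="player")
    skill = model.add_deterministic("skill", skill_raw * sd, dims="player")
    logit_skill = pt.take(skill, winner_ids) - pt.take(skill, loser_ids)
    model.add_observed("win", Bernoulli(logit_p=logit_skill),
                       np.ones(winner_ids.shape[0]))
    return model


def build_dirichlet_multinomial(counts, trees=None, forests=None,
                                total_count=None) -> ProbModel:
    """Marginalized Dirichlet-multinomial over a forest x species table."""
    counts = np.asarray(counts)
    n, k = counts.shape
    if trees is None:
        trees = np.array([f"tree{i}" for i in range(k)])
    if forests is None:
        forests = np.arange(n)
    if total_count is None:
        totals = counts.sum(axis=1)
        if not np.all(totals == totals[0]):
            raise ValueError("rows must share total_count; pass it explicitly")
        total_count = int(totals[0])
    model = ProbModel(coords={"tree": np.asarray(trees),
                              "forest": np.asarray(forests)})
    frac = model.add_free("frac", Dirichlet(np.ones(k)), dims="tree")
    conc = model.add_free("conc", LogNormal(mu=1, sigma=1))
    model.add_observed(
        "counts", DirichletMultinomial(n=total_count, a=frac * conc),
        counts.astype(float), dims=("forest", "tree"))
    return model


# ---------------------------------------------------------------------------
# Synthetic generators
# ---------------------------------------------------------------------------


@dataclass
class BradleyTerryConfig:
    """Latent-skill match generator: skills ~ Normal(0, sigma^2).

    With sigma = 1, about 95% of skills fall in (-2, 2); a gap of 2 between
    two players implies the stronger one wins with probability
    logistic(2) ~ 88.1%.
    """

    n_players: int = 20
    n_matches: int = 2000
    sigma: float = 1.0

    def __post_init__(self):
        if self.n_players < 2 or self.n_matches < 1 or self.sigma <= 0:
            raise ValueError("invalid Bradley-Terry configuration")


def simulate_bradley_terry(config: BradleyTerryConfig | None = None,
                           seed=None):
    """Seeded match outcomes; returns (winner_ids, loser_ids, skills)."""
    from scipy.special import expit
    config = config or BradleyTerryConfig()
    rng = np.random.default_rng(seed)
    skills = rng.normal(0.0, config.sigma, size=config.n_players)
    i = rng.integers(0, config.n_players, size=config.n_matches)
    j = rng.integers(0, config.n_players - 1, size=config.n_matches)
    j = np.where(j >= i, j + 1, j)  # distinct opponents
    p_i_wins = expit(skills[i] - skills[j])
    i_wins = rng.random(config.n_matches) < p_i_wins
    winner = np.where(i_wins, i, j)
    loser = np.where(i_wins, j, i)
    return winner, loser, skills


@dataclass
class ForestCountsConfig:
    """Dirichlet-multinomial count-table generator.

    ``conc`` controls over-dispersion: as conc -> infinity the rows approach
    plain multinomial draws at the expected fractions.
    """

    n_forests: int = 10
    k_species: int = 5
    total_count: int = 100
    frac: np.ndarray | None = None
    conc: float = 10.0

    def __post_init__(self):
        if self.frac is None:
            # skewed but non-degenerate community composition
            base = np.linspace(2.0, 0.5, self.k_species)
            self.frac = base / base.sum()
        self.frac = np.asarray(self.frac, dtype=float)
        if len(self.frac) != self.k_species or self.conc <= 0:
            raise ValueError("invalid forest-counts configuration")


def simulate_forest_counts(config: ForestCountsConfig | None = None,
                           seed=None) -> np.ndarray:
    """Seeded (n_forests, k_species) count matrix with fixed row sums."""
    config = config or ForestCountsConfig()
    rng = np.random.default_rng(seed)
    out = np.empty((config.n_forests, config.k_species), dtype=int)
    alpha = config.frac * config.conc
    for row in range(config.n_forests):
        p = rng.dirichlet(alpha)
        out[row] = rng.multinomial(config.total_count, p)
    return out
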