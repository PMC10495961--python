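"""MCMC transition kernels and their automatic assignment.

Continuous free variables are grouped into one No-U-Turn sampler (NUTS)
block: dynamic Hamiltonian Monte Carlo with multinomial sampling over the
doubling trajectory, a generalized U-turn criterion also checked across
sub-tree boundaries, dual-averaging step-size adaptation and diagonal
mass-matrix estimation over expanding windows.  Discrete variables each get
an adaptive random-walk Metropolis kernel (integer-rounded proposals).  A
model mixing both is sampled by a Metropolis-within-Gibbs compound that
applies each kernel in turn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import ProbModel, FreeVar

__all__ = [
    "NUTS", "Metropolis", "CompoundStep", "assign_steps",
    "leapfrog", "adapt_mass_diag", "DualAveraging",
]


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------


class _Block:
    """Ravel/unravel a set of transformed variables to one flat vector."""

    def __init__(self, names: list[str], point: dict):
        self.names = names
        self.shapes = [np.shape(point[n]) for n in names]
        self.sizes = [int(np.prod(s)) if s else 1 for s in self.shapes]
        self.n = sum(self.sizes)

    def ravel(self, point: dict) -> np.ndarray:
        return np.concatenate([np.ravel(np.asarray(point[n], dtype=float))
                               for n in self.names]) if self.names else np.empty(0)

    def unravel(self, vec: np.ndarray, point: dict) -> dict:
        out = dict(point)
        i = 0
        for name, shape, size in zip(self.names, self.shapes, self.sizes):
            chunk = vec[i:i + size]
            out[name] = chunk.reshape(shape) if shape else np.float64(chunk[0])
            i += size
        return out


def leapfrog(position, momentum, stepsize, grad_fn, mass_diag):
    """One symplectic leapfrog step with a diagonal mass matrix.

    Time-reversible: negating the returned momentum and stepping again
    recovers the starting state to floating-point accuracy.
    """
    position = np.asarray(position, dtype=float)
    momentum = np.asarray(momentum, dtype=float)
    g = np.asarray(grad_fn(position), dtype=float)
    if not np.all(np.isfinite(g)):
        raise FloatingPointError("non-finite gradient in leapfrog")
    p_half = momentum + 0.5 * stepsize * g
    q_new = position + stepsize * p_half / mass_diag
    g_new = np.asarray(grad_fn(q_new), dtype=float)
    if not np.all(np.isfinite(g_new)):
        raise FloatingPointError("non-finite gradient in leapfrog")
    p_new = p_half + 0.5 * stepsize * g_new
    return q_new, p_new


def adapt_mass_diag(tune_draws) -> np.ndarray:
    """Regularized per-coordinate variance estimate (always positive)."""
    draws = np.atleast_2d(np.asarray(tune_draws, dtype=float))
    n = draws.shape[0]
    if n > 1:
        var = draws.var(axis=0, ddof=1)
    else:
        var = np.ones(draws.shape[1])
    # shrink toward a small positive floor, as in windowed HMC adaptation
    return (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))


class DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, eps0: float, target: float = 0.8,
                 gamma: float = 0.05, t0: float = 10.0, kappa: float = 0.75):
        self.mu = math.log(10.0 * eps0)
        self.target = target
        self.gamma = gamma
        self.t0 = t0
        self.kappa = kappa
        self.t = 0
        self.h_bar = 0.0
        self.log_eps = math.log(eps0)
        self.log_eps_bar = 0.0

    def update(self, accept_stat: float) -> float:
        self.t += 1
        frac = 1.0 / (self.t + self.t0)
        self.h_bar = (1 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - math.sqrt(self.t) / self.gamma * self.h_bar
        w = self.t ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return math.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return math.exp(self.log_eps_bar)


# ---------------------------------------------------------------------------
# NUTS
# ---------------------------------------------------------------------------


@dataclass
class NUTSConfig:
    target_accept: float = 0.8
    max_treedepth: int = 10
    divergence_threshold: float = 1000.0
    gamma: float = 0.05
    t0: float = 10.0
    kappa: float = 0.75

    def __post_init__(self):
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")
        if self.max_treedepth < 1:
            raise ValueError("max_treedepth must be >= 1")


class _Tree:
    __slots__ = ("q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
                 "q_prop", "logp_prop", "g_prop", "logw", "rho",
                 "turning", "diverging", "n_steps", "sum_accept")

    def __init__(self, q, p, g, logw, rho):
        self.q_minus = self.q_plus = self.q_prop = q
        self.p_minus = self.p_plus = p
        self.g_minus = self.g_plus = self.g_prop = g
        self.logp_prop = None
        self.logw = logw
        self.rho = rho
        self.turning = False
        self.diverging = False
        self.n_steps = 0
        self.sum_accept = 0.0


class NUTS:
    """No-U-Turn sampler for one block of continuous variables."""

    name = "NUTS"

    def __init__(self, var_names=None, target_accept=0.8, max_treedepth=10,
                 divergence_threshold=1000.0, step_size=None):
        self.var_names = var_names
        self.config = NUTSConfig(target_accept=target_accept,
                                 max_treedepth=max_treedepth,
                                 divergence_threshold=divergence_threshold)
        self._fixed_eps = step_size

    # -- binding ------------------------------------------------------------

    def bind(self, model: ProbModel, point: dict, rng: np.random.Generator,
             n_tune: int):
        if self.var_names is None:
            self.var_names = [fv.transformed for fv in model.continuous_vars]
        self.block = _Block(self.var_names, point)
        self._logp_grad_full = model.compile_logp_grad()
        self.rng = rng
        self.mass = np.ones(self.block.n)
        self._point_template = dict(point)
        q0 = self.block.ravel(point)
        if self._fixed_eps is None:
            eps0 = self._find_initial_stepsize(q0, point)
        else:
            eps0 = self._fixed_eps
        self.eps = eps0
        self.da = DualAveraging(eps0, target=self.config.target_accept,
                                gamma=self.config.gamma, t0=self.config.t0,
                                kappa=self.config.kappa)
        self._windows = self._adapt_windows(n_tune)
        self._window_draws: list[np.ndarray] = []
        self._iter = 0
        self._n_tune = n_tune

    @staticmethod
    def _adapt_windows(n_tune: int) -> set[int]:
        """Iterations at which the mass matrix is re-estimated (window ends)."""
        ends = set()
        if n_tune < 40:
            if n_tune > 10:
                ends.add(n_tune // 2)
            return ends
        start, term = 25, 50
        t = start
        w = 25
        while t + w + term < n_tune:
            t += w
            ends.add(t)
            w *= 2
        ends.add(n_tune - term)
        return ends

    def _logp_grad_vec(self, q, point):
        pt_full = self.block.unravel(q, point)
        logp, gdict = self._logp_grad_full(pt_full)
        g = np.concatenate([np.ravel(np.asarray(gdict[n], dtype=float))
                            for n in self.block.names])
        return float(logp), g

    def _find_initial_stepsize(self, q0, point, eps=1.0):
        logp0, g0 = self._logp_grad_vec(q0, point)
        p0 = self.rng.normal(size=self.block.n) * np.sqrt(self.mass)
        h0 = logp0 - 0.5 * np.sum(p0 * p0 / self.mass)

        def accept(eps):
            try:
                g = g0
                p_half = p0 + 0.5 * eps * g
                q1 = q0 + eps * p_half / self.mass
                logp1, g1 = self._logp_grad_vec(q1, point)
                p1 = p_half + 0.5 * eps * g1
                h1 = logp1 - 0.5 * np.sum(p1 * p1 / self.mass)
                return math.exp(min(0.0, h1 - h0))
            except (FloatingPointError, OverflowError):
                return 0.0

        a = accept(eps)
        direction = 1 if a > 0.5 else -1
        for _ in range(50):
            eps_new = eps * (2.0 ** direction)
            a = accept(eps_new)
            if (direction == 1 and a <= 0.5) or (direction == -1 and a >= 0.5):
                break
            eps = eps_new
        return max(eps, 1e-8)

    # -- one transition ------------------------------------------------------

    def step(self, point: dict, tuning: bool):
        cfg = self.config
        q0 = self.block.ravel(point)
        logp0, g0 = self._logp_grad_vec(q0, point)
        p0 = self.rng.normal(size=self.block.n) * np.sqrt(self.mass)
        h0 = logp0 - 0.5 * np.sum(p0 * p0 / self.mass)

        tree = _Tree(q0, p0, g0, logw=0.0, rho=p0.copy())
        tree.logp_prop = logp0
        depth = 0
        while depth < cfg.max_treedepth:
            direction = 1 if self.rng.random() < 0.5 else -1
            sub = self._build_tree(tree, direction, depth, h0, point)
            tree.n_steps += sub.n_steps
            tree.sum_accept += sub.sum_accept
            if sub.diverging:
                tree.diverging = True
                break
            if sub.turning:
                break
            # progressive multinomial sampling, biased toward the new subtree
            log_ratio = sub.logw - tree.logw
            if math.log(self.rng.random() + 1e-300) < log_ratio:
                tree.q_prop = sub.q_prop
                tree.logp_prop = sub.logp_prop
                tree.g_prop = sub.g_prop
            tree.logw = np.logaddexp(tree.logw, sub.logw)
            rho = tree.rho + sub.rho
            if self._turning(tree.p_minus if direction == 1 else sub.p_minus,
                             tree.p_plus if direction == -1 else sub.p_plus,
                             rho):
                tree.rho = rho
                self._absorb_edges(tree, sub, direction)
                break
            tree.rho = rho
            self._absorb_edges(tree, sub, direction)
            depth += 1
        else:
            depth = cfg.max_treedepth

        n_steps = max(tree.n_steps, 1)
        accept_stat = tree.sum_accept / n_steps if tree.sum_accept else 0.0
        new_point = self.block.unravel(tree.q_prop, point)
        energy = -(tree.logp_prop
                   if tree.logp_prop is not None else logp0) + \
            0.5 * np.sum(p0 * p0 / self.mass)
        stats = {
            "step_size": self.eps,
            "tree_depth": depth + 1,
            "n_steps": n_steps,
            "mean_tree_accept": accept_stat,
            "diverging": bool(tree.diverging),
            "energy": float(energy),
        }
        if tuning:
            self.eps = self.da.update(accept_stat)
            self._window_draws.append(self.block.ravel(new_point))
            self._iter += 1
            if self._iter in self._windows and len(self._window_draws) > 1:
                self.mass = adapt_mass_diag(np.asarray(self._window_draws))
                self._window_draws = []
                # re-anchor step-size search after the metric changes
                self.da = DualAveraging(self.eps, target=cfg.target_accept,
                                        gamma=cfg.gamma, t0=cfg.t0,
                                        kappa=cfg.kappa)
            if self._iter == self._n_tune:
                self.eps = self.da.adapted
        return new_point, stats

    def _absorb_edges(self, tree: _Tree, sub: _Tree, direction: int):
        if direction == 1:
            tree.q_plus, tree.p_plus, tree.g_plus = \
                sub.q_plus, sub.p_plus, sub.g_plus
        else:
            tree.q_minus, tree.p_minus, tree.g_minus = \
                sub.q_minus, sub.p_minus, sub.g_minus

    def _turning(self, p_minus, p_plus, rho) -> bool:
        # generalized U-turn: projections of the boundary momenta on the
        # trajectory's total momentum must both stay positive
        v_minus = p_minus / self.mass
        v_plus = p_plus / self.mass
        return (np.dot(v_minus, rho) <= 0) or (np.dot(v_plus, rho) <= 0)

    def _build_tree(self, tree: _Tree, direction: int, depth: int, h0: float,
                    point: dict) -> _Tree:
        if depth == 0:
            q = tree.q_plus if direction == 1 else tree.q_minus
            p = tree.p_plus if direction == 1 else tree.p_minus
            g = tree.g_plus if direction == 1 else tree.g_minus
            eps = direction * self.eps
            try:
                p_half = p + 0.5 * eps * g
                q1 = q + eps * p_half / self.mass
                logp1, g1 = self._logp_grad_vec(q1, point)
                p1 = p_half + 0.5 * eps * g1
            except (FloatingPointError, OverflowError):
                leaf = _Tree(q, p, g, logw=-np.inf, rho=np.zeros_like(p))
                leaf.diverging = True
                leaf.n_steps = 1
                return leaf
            if not np.isfinite(logp1):
                h1 = -np.inf
            else:
                h1 = logp1 - 0.5 * np.sum(p1 * p1 / self.mass)
            energy_error = h0 - h1 if np.isfinite(h1) else np.inf
            leaf = _Tree(q1, p1, g1, logw=(h1 - h0), rho=p1.copy())
            leaf.logp_prop = logp1 if np.isfinite(logp1) else None
            leaf.n_steps = 1
            leaf.sum_accept = math.exp(min(0.0, h1 - h0)) if np.isfinite(h1) else 0.0
            if energy_error > self.config.divergence_threshold:
                leaf.diverging = True
            return leaf
        first = self._build_tree(tree, direction, depth - 1, h0, point)
        if first.turning or first.diverging:
            return first
        # graft the first half in so the second half extends from its edge
        carrier = _Tree(first.q_minus, first.p_minus, first.g_minus,
                        logw=first.logw, rho=first.rho)
        carrier.q_plus, carrier.p_plus, carrier.g_plus = \
            first.q_plus, first.p_plus, first.g_plus
        second = self._build_tree(carrier, direction, depth - 1, h0, point)
        combined = first
        combined.n_steps = first.n_steps + second.n_steps
        combined.sum_accept = first.sum_accept + second.sum_accept
        if second.diverging:
            combined.diverging = True
            return combined
        if second.turning:
            combined.turning = True
            return combined
        log_ratio = second.logw - np.logaddexp(first.logw, second.logw)
        if math.log(self.rng.random() + 1e-300) < log_ratio:
            combined.q_prop = second.q_prop
            combined.logp_prop = second.logp_prop
            combined.g_prop = second.g_prop
        combined.logw = np.logaddexp(first.logw, second.logw)
        rho = first.rho + second.rho
        # corrected U-turn check: full tree plus both sub-tree boundaries
        if direction == 1:
            p_l, p_r = first.p_minus, second.p_plus
            p_lm, p_rm = first.p_plus, second.p_minus
        else:
            p_l, p_r = second.p_minus, first.p_plus
            p_lm, p_rm = second.p_plus, first.p_minus
        turning = self._turning(p_l, p_r, rho)
        turning = turning or self._turning(p_l, p_rm, first.rho + p_rm)
        turning = turning or self._turning(p_lm, p_r, second.rho + p_lm)
        combined.turning = bool(turning)
        if direction == 1:
            combined.q_plus, combined.p_plus, combined.g_plus = \
                second.q_plus, second.p_plus, second.g_plus
        else:
            combined.q_minus, combined.p_minus, combined.g_minus = \
                second.q_minus, second.p_minus, second.g_minus
        combined.rho = rho
        return combined


# ---------------------------------------------------------------------------
# Metropolis
# ---------------------------------------------------------------------------


@dataclass
class MetropolisConfig:
    scale: float = 1.0
    tune_interval: int = 100

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("proposal scale must be > 0")


def _tune_scale(scale: float, acc_rate: float) -> float:
    """Classic acceptance-band tuning toward roughly 0.1-0.7."""
    if acc_rate < 0.001:
        return scale * 0.1
    if acc_rate < 0.05:
        return scale * 0.5
    if acc_rate < 0.2:
        return scale * 0.9
    if acc_rate > 0.95:
        return scale * 10.0
    if acc_rate > 0.75:
        return scale * 2.0
    if acc_rate > 0.5:
        return scale * 1.1
    return scale


class Metropolis:
    """Adaptive random-walk Metropolis for one block of variables.

    Continuous support uses Gaussian increments; integer support uses
    rounded-Gaussian increments so proposals stay on the lattice.
    """

    name = "Metropolis"

    def __init__(self, var_names=None, scale=1.0, tune_interval=100,
                 integer=None):
        self.var_names = var_names
        self.config = MetropolisConfig(scale=scale, tune_interval=tune_interval)
        self.integer = integer

    def bind(self, model: ProbModel, point: dict, rng: np.random.Generator,
             n_tune: int):
        if self.var_names is None:
            self.var_names = [fv.transformed for fv in model.free.values()]
        self.block = _Block(self.var_names, point)
        self._logp = model.compile_logp()
        self.rng = rng
        if self.integer is None:
            by_name = {fv.transformed: fv for fv in model.free.values()}
            self.integer = all(not by_name[n].rv.dist.support.continuous
                               for n in self.var_names)
        self.scale = self.config.scale
        self._acc = 0
        self._tries = 0

    def step(self, point: dict, tuning: bool):
        q = self.block.ravel(point)
        logp0 = float(self._logp(point))
        delta = self.rng.normal(0.0, self.scale, size=self.block.n)
        if self.integer:
            delta = np.round(delta)
        q1 = q + delta
        point1 = self.block.unravel(q1, point)
        logp1 = float(self._logp(point1))
        accept = math.log(self.rng.random() + 1e-300) < (logp1 - logp0)
        self._tries += 1
        if accept:
            point = point1
            self._acc += 1
        stats = {f"accept_{self.var_names[0]}":
                 float(min(1.0, math.exp(min(0.0, logp1 - logp0)))),
                 f"scale_{self.var_names[0]}": self.scale}
        if tuning and self._tries % self.config.tune_interval == 0:
            self.scale = _tune_scale(self.scale,
                                     self._acc / self.config.tune_interval)
            self._acc = 0
        return point, stats


# ---------------------------------------------------------------------------
# Compound assignment
# ---------------------------------------------------------------------------


class CompoundStep:
    """Metropolis-within-Gibbs: apply each kernel in sequence per iteration."""

    def __init__(self, steps):
        self.steps = list(steps)

    def bind(self, model, point, rng, n_tune):
        children = rng.spawn(len(self.steps)) if hasattr(rng, "spawn") else \
            [np.random.default_rng(s) for s in
             np.random.SeedSequence(rng).spawn(len(self.steps))]
        for s, r in zip(self.steps, children):
            s.bind(model, point, r, n_tune)

    def step(self, point, tuning):
        stats = {}
        for s in self.steps:
            point, st = s.step(point, tuning)
            stats.update(st)
        return point, stats

    @property
    def description(self) -> str:
        from .transforms import parse_transformed_name
        parts = []
        for s in self.steps:
            names = [parse_transformed_name(n)[0] for n in s.var_names]
            parts.append(f"{s.name}: [{', '.join(names)}]")
        return "; ".join(parts)


def assign_steps(model: ProbModel, overrides=None) -> CompoundStep:
    """Group continuous variables under NUTS, discrete under Metropolis."""
    if not model.free:
        raise ValueError("model has no free variables to sample")
    overrides = overrides or {}
    taken = set()
    steps = []
    for step in (overrides.values() if isinstance(overrides, dict)
                 else overrides):
        steps.append(step)
        taken.update(step.var_names or ())
    cont = [fv.transformed for fv in model.continuous_vars
            if fv.transformed not in taken]
    if cont:
        steps.append(NUTS(var_names=cont))
    for fv in model.discrete_vars:
        if fv.transformed not in taken:
            steps.append(Metropolis(var_names=[fv.transformed]))
    return CompoundStep(steps)
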