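"""No-U-Turn sampler with dual-averaging step size and diagonal metric.

A self-contained implementation of multinomial NUTS (the variant used by
modern probabilistic programming systems): trajectories are doubled until a
U-turn or divergence, and the returned state is drawn from the whole
trajectory with weights proportional to the canonical density.  Warmup
follows the usual three-phase schedule — an initial step-size-only buffer,
expanding windows that estimate a diagonal inverse metric from the warmup
draws, and a final step-size-only buffer.

Everything is driven by a ``logp_and_grad(x) -> (float, ndarray)`` callable,
so the same sampler serves both the hierarchical LBA model and the Poisson
preference models.  Runs are deterministic given the ``numpy`` Generator
passed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_DELTA_H = 1000.0  # divergence threshold on the Hamiltonian error


@dataclass
class SamplerConfig:
    """MCMC configuration; the defaults mirror the fitting recipe used
    throughout: 4 chains x (1000 warmup + 2000 retained) = 8000 draws."""

    chains: int = 4
    warmup_iterations: int = 1000
    sampling_iterations: int = 2000
    seed: int = 0
    target_acceptance: float = 0.8
    # depth 7 = 128 leapfrog steps, twice the trajectory length this
    # model's posterior settles on after adaptation; capping bounds the
    # cost of early-warmup excursions on a single CPU
    max_tree_depth: int = 7
    init_scale: float = 0.5
    # advanced: start adaptation from a previously adapted diagonal
    # inverse metric (e.g. from a fit of a same-design dataset); warmup
    # windows still re-estimate it, so this only shortens adaptation
    initial_inv_metric: object = None

    @property
    def total_draws(self) -> int:
        return self.chains * self.sampling_iterations


@dataclass
class ChainStats:
    divergences: int = 0
    max_treedepth_hits: int = 0
    step_size: float = float("nan")
    accept_rate: float = float("nan")
    treedepths: list = field(default_factory=list)
    inv_metric: object = None  # adapted diagonal inverse metric


class _DualAveraging:
    """Nesterov dual averaging targeting a fixed acceptance statistic."""

    def __init__(self, eps0: float, target: float, gamma: float = 0.05,
                 t0: float = 10.0, kappa: float = 0.75):
        self.mu = np.log(10.0 * eps0)
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.log_eps = np.log(eps0)
        self.log_eps_bar = 0.0
        self.h_bar = 0.0
        self.count = 0

    def update(self, accept_stat: float) -> float:
        self.count += 1
        eta = 1.0 / (self.count + self.t0)
        self.h_bar = (1 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.count) / self.gamma * self.h_bar
        w = self.count ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1 - w) * self.log_eps_bar
        return np.exp(self.log_eps)

    @property
    def adapted(self) -> float:
        return float(np.exp(self.log_eps_bar))


def _leapfrog(logp_and_grad, x, p, grad, eps, inv_metric):
    p = p + 0.5 * eps * grad
    x = x + eps * inv_metric * p
    lp, grad = logp_and_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, lp, grad


def _find_initial_step(logp_and_grad, x0, lp0, grad0, inv_metric, rng):
    eps = 1.0
    p0 = rng.standard_normal(len(x0)) / np.sqrt(inv_metric)
    h0 = lp0 - 0.5 * float(np.sum(p0 * p0 * inv_metric))
    _, p1, lp1, _ = _leapfrog(logp_and_grad, x0, p0, grad0, eps, inv_metric)
    h1 = lp1 - 0.5 * float(np.sum(p1 * p1 * inv_metric))
    if not np.isfinite(h1):
        h1 = -np.inf
    direction = 1.0 if (h1 - h0) > np.log(0.5) else -1.0
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, lp1, _ = _leapfrog(logp_and_grad, x0, p0, grad0, eps, inv_metric)
        h1 = lp1 - 0.5 * float(np.sum(p1 * p1 * inv_metric))
        if not np.isfinite(h1):
            h1 = -np.inf
        if direction * (h1 - h0) < direction * np.log(0.5):
            break
    return max(min(eps, 10.0), 1e-8)


class _Tree:
    __slots__ = ("x_minus", "p_minus", "g_minus", "x_plus", "p_plus", "g_plus",
                 "x_prop", "g_prop", "lp_prop", "log_weight", "sum_accept",
                 "n_leapfrog", "turned", "diverged")


def _build_tree(logp_and_grad, x, p, grad, depth, direction, eps, h0,
                inv_metric, rng):
    if depth == 0:
        x1, p1, lp1, g1 = _leapfrog(logp_and_grad, x, p, grad,
                                    direction * eps, inv_metric)
        h1 = lp1 - 0.5 * float(np.sum(p1 * p1 * inv_metric))
        if not np.isfinite(h1):
            h1 = -np.inf
        t = _Tree()
        t.x_minus = t.x_plus = t.x_prop = x1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.lp_prop = lp1
        t.log_weight = h1 - h0
        t.sum_accept = float(np.exp(min(0.0, h1 - h0)))
        t.n_leapfrog = 1
        t.turned = False
        t.diverged = (h0 - h1) > MAX_DELTA_H
        return t

    inner = _build_tree(logp_and_grad, x, p, grad, depth - 1, direction, eps,
                        h0, inv_metric, rng)
    if inner.diverged or inner.turned:
        return inner
    if direction == 1:
        outer = _build_tree(logp_and_grad, inner.x_plus, inner.p_plus,
                            inner.g_plus, depth - 1, direction, eps, h0,
                            inv_metric, rng)
    else:
        outer = _build_tree(logp_and_grad, inner.x_minus, inner.p_minus,
                            inner.g_minus, depth - 1, direction, eps, h0,
                            inv_metric, rng)
    t = _Tree()
    if direction == 1:
        t.x_minus, t.p_minus, t.g_minus = inner.x_minus, inner.p_minus, inner.g_minus
        t.x_plus, t.p_plus, t.g_plus = outer.x_plus, outer.p_plus, outer.g_plus
    else:
        t.x_minus, t.p_minus, t.g_minus = outer.x_minus, outer.p_minus, outer.g_minus
        t.x_plus, t.p_plus, t.g_plus = inner.x_plus, inner.p_plus, inner.g_plus
    t.log_weight = np.logaddexp(inner.log_weight, outer.log_weight)
    # multinomial sampling within the trajectory
    if np.log(rng.random()) < outer.log_weight - t.log_weight:
        t.x_prop, t.g_prop, t.lp_prop = outer.x_prop, outer.g_prop, outer.lp_prop
    else:
        t.x_prop, t.g_prop, t.lp_prop = inner.x_prop, inner.g_prop, inner.lp_prop
    t.sum_accept = inner.sum_accept + outer.sum_accept
    t.n_leapfrog = inner.n_leapfrog + outer.n_leapfrog
    t.diverged = outer.diverged
    dx = t.x_plus - t.x_minus
    t.turned = (float(np.dot(dx, inv_metric * t.p_minus)) < 0
                or float(np.dot(dx, inv_metric * t.p_plus)) < 0)
    return t


def sample_chain(logp_and_grad, x0: np.ndarray, config: SamplerConfig,
                 rng: np.random.Generator):
    """Run one NUTS chain; returns (draws, logps, ChainStats).

    ``draws`` has shape (sampling_iterations, dim) and contains only
    post-warmup states.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        return _sample_chain(logp_and_grad, x0, config, rng)


def _sample_chain(logp_and_grad, x0, config, rng):
    x = np.asarray(x0, dtype=float).copy()
    dim = len(x)
    lp, grad = logp_and_grad(x)
    if not np.isfinite(lp):
        raise FloatingPointError(
            "non-finite log posterior at the initial point; "
            f"logp={lp} at ||x||={np.linalg.norm(x):.3f}"
        )
    if config.initial_inv_metric is not None:
        inv_metric = np.asarray(config.initial_inv_metric, dtype=float).copy()
        if inv_metric.shape != (dim,):
            raise ValueError("initial_inv_metric has the wrong dimension")
    else:
        inv_metric = np.ones(dim)

    n_warm = config.warmup_iterations
    n_samp = config.sampling_iterations
    eps = _find_initial_step(logp_and_grad, x, lp, grad, inv_metric, rng)
    da = _DualAveraging(eps, config.target_acceptance)

    # windowed adaptation with fixed buffers (75 step-size-only iterations,
    # then doubling variance-estimation windows from 25, then a 50-iteration
    # final step-size window), scaled down proportionally for short warmups
    if n_warm >= 300:
        init_buf, term_buf, w = 75, 50, 25
    else:
        # short warmups: proportional buffers adapt the metric earlier
        init_buf = max(1, int(0.15 * n_warm))
        term_buf = max(1, int(0.10 * n_warm))
        w = max(1, int(0.17 * (n_warm - init_buf - term_buf)))
    window_ends = []
    pos = init_buf
    while pos + w < n_warm - term_buf:
        window_ends.append(pos + w)
        pos += w
        w *= 2
    window_ends.append(n_warm - term_buf)

    draws = np.empty((n_samp, dim))
    logps = np.empty(n_samp)
    stats = ChainStats()
    accum = []  # warmup states for the current variance window
    accepts = []
    win_idx = 0

    for it in range(n_warm + n_samp):
        warming = it < n_warm
        if it == n_warm:
            eps = da.adapted
            stats.step_size = eps
        p0 = rng.standard_normal(dim) / np.sqrt(inv_metric)
        h0 = lp - 0.5 * float(np.sum(p0 * p0 * inv_metric))
        x_minus = x_plus = x
        p_minus = p_plus = p0
        g_minus = g_plus = grad
        x_prop, g_prop, lp_prop = x, grad, lp
        log_weight = 0.0
        sum_accept = 0.0
        n_leap = 0
        depth = 0
        diverged = False
        while depth < config.max_tree_depth:
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                t = _build_tree(logp_and_grad, x_plus, p_plus, g_plus, depth,
                                1, eps, h0, inv_metric, rng)
                x_plus, p_plus, g_plus = t.x_plus, t.p_plus, t.g_plus
            else:
                t = _build_tree(logp_and_grad, x_minus, p_minus, g_minus,
                                depth, -1, eps, h0, inv_metric, rng)
                x_minus, p_minus, g_minus = t.x_minus, t.p_minus, t.g_minus
            sum_accept += t.sum_accept
            n_leap += t.n_leapfrog
            if t.diverged:
                diverged = True
                break
            # biased progressive sampling toward the new subtree
            if np.log(rng.random()) < t.log_weight - log_weight:
                x_prop, g_prop, lp_prop = t.x_prop, t.g_prop, t.lp_prop
            log_weight = np.logaddexp(log_weight, t.log_weight)
            if t.turned:
                break
            dx = x_plus - x_minus
            if (float(np.dot(dx, inv_metric * p_minus)) < 0
                    or float(np.dot(dx, inv_metric * p_plus)) < 0):
                break
            depth += 1
        x, grad, lp = x_prop, g_prop, lp_prop
        accept_stat = sum_accept / max(n_leap, 1)

        if warming:
            eps = da.update(accept_stat)
            if win_idx < len(window_ends) and it >= init_buf:
                accum.append(x.copy())
                if it + 1 == window_ends[win_idx]:
                    arr = np.asarray(accum)
                    if len(arr) > 4:
                        var = np.var(arr, axis=0, ddof=1)
                        n = len(arr)
                        inv_metric = (n / (n + 5.0)) * var \
                            + 1e-3 * (5.0 / (n + 5.0))
                        inv_metric = np.maximum(inv_metric, 1e-10)
                    accum = []
                    win_idx += 1
                    eps = _find_initial_step(logp_and_grad, x, lp, grad,
                                             inv_metric, rng)
                    da = _DualAveraging(eps, config.target_acceptance)
        else:
            i = it - n_warm
            draws[i] = x
            logps[i] = lp
            accepts.append(accept_stat)
            if diverged:
                stats.divergences += 1
            if depth >= config.max_tree_depth:
                stats.max_treedepth_hits += 1
            stats.treedepths.append(depth)

    stats.accept_rate = float(np.mean(accepts)) if accepts else float("nan")
    stats.inv_metric = inv_metric.copy()
    return draws, logps, stats
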