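"""A compact No-U-Turn sampler (multinomial variant) with dual-averaging
step-size adaptation and diagonal mass-matrix estimation during warm-up.

The target is supplied as a single callable returning the joint log density
and its gradient.  Gradients are analytic throughout this package (Poisson
log link plus Gaussian/exponential priors), so the sampler needs no autodiff.
Everything is driven by an explicit ``numpy.random.Generator``; identical
seed and settings give identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["sample_nuts", "NutsStats"]

_DIVERGENCE_DH = 1000.0


@dataclass
class NutsStats:
    step_size: float
    mean_accept: float
    n_divergent: int
    mean_treedepth: float
    inv_mass: np.ndarray = field(repr=False, default=None)


def _hamiltonian(lp: float, r: np.ndarray, inv_mass: np.ndarray) -> float:
    with np.errstate(over="ignore"):
        h = -lp + 0.5 * float(r @ (inv_mass * r))
    return h if np.isfinite(h) else np.inf


class _Tree:
    __slots__ = (
        "theta_m", "r_m", "g_m", "theta_p", "r_p", "g_p",
        "theta_prop", "lp_prop", "g_prop", "log_w",
        "sum_accept", "n_accept", "diverged", "turning",
    )


def _leapfrog(theta, r, g, eps, logp_grad, inv_mass):
    r = r + 0.5 * eps * g
    theta = theta + eps * (inv_mass * r)
    lp, g = logp_grad(theta)
    if not np.isfinite(lp):
        lp, g = -np.inf, np.zeros_like(theta)
    else:
        r = r + 0.5 * eps * g
    return theta, r, lp, g


def _build_tree(theta, r, g, lp, direction, depth, eps, h0, logp_grad, inv_mass, rng):
    if depth == 0:
        theta1, r1, lp1, g1 = _leapfrog(theta, r, g, direction * eps, logp_grad, inv_mass)
        h1 = _hamiltonian(lp1, r1, inv_mass) if np.isfinite(lp1) else np.inf
        t = _Tree()
        t.theta_m = t.theta_p = t.theta_prop = theta1
        t.r_m = t.r_p = r1
        t.g_m = t.g_p = t.g_prop = g1
        t.lp_prop = lp1
        t.log_w = h0 - h1  # log multinomial weight relative to start
        t.sum_accept = min(1.0, np.exp(min(h0 - h1, 0.0)))
        t.n_accept = 1
        t.diverged = (h1 - h0) > _DIVERGENCE_DH or not np.isfinite(h1)
        t.turning = False
        return t

    left = _build_tree(theta, r, g, lp, direction, depth - 1, eps, h0,
                       logp_grad, inv_mass, rng)
    if left.diverged or left.turning:
        return left
    if direction == 1:
        right = _build_tree(left.theta_p, left.r_p, left.g_p, None, direction,
                            depth - 1, eps, h0, logp_grad, inv_mass, rng)
        left.theta_p, left.r_p, left.g_p = right.theta_p, right.r_p, right.g_p
    else:
        right = _build_tree(left.theta_m, left.r_m, left.g_m, None, direction,
                            depth - 1, eps, h0, logp_grad, inv_mass, rng)
        left.theta_m, left.r_m, left.g_m = right.theta_m, right.r_m, right.g_m

    total = np.logaddexp(left.log_w, right.log_w)
    if np.log(rng.uniform()) < right.log_w - total:
        left.theta_prop, left.lp_prop, left.g_prop = (
            right.theta_prop, right.lp_prop, right.g_prop,
        )
    left.log_w = total
    left.sum_accept += right.sum_accept
    left.n_accept += right.n_accept
    left.diverged = right.diverged
    dtheta = left.theta_p - left.theta_m
    left.turning = (
        right.turning
        or dtheta @ (inv_mass * left.r_m) < 0
        or dtheta @ (inv_mass * left.r_p) < 0
    )
    return left


def _nuts_step(theta, lp, g, eps, logp_grad, inv_mass, rng, max_treedepth):
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = _hamiltonian(lp, r, inv_mass)
    theta_m = theta_p = theta
    r_m = r_p = r
    g_m = g_p = g
    theta_cur, lp_cur, g_cur = theta, lp, g
    log_w = 0.0
    sum_accept, n_accept, n_div = 0.0, 0, 0
    depth = 0
    while depth < max_treedepth:
        direction = 1 if rng.uniform() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(theta_p, r_p, g_p, None, direction, depth, eps,
                              h0, logp_grad, inv_mass, rng)
            theta_p, r_p, g_p = sub.theta_p, sub.r_p, sub.g_p
        else:
            sub = _build_tree(theta_m, r_m, g_m, None, direction, depth, eps,
                              h0, logp_grad, inv_mass, rng)
            theta_m, r_m, g_m = sub.theta_m, sub.r_m, sub.g_m
        sum_accept += sub.sum_accept
        n_accept += sub.n_accept
        if sub.diverged:
            n_div = 1
            break
        if sub.turning:
            break
        # biased progressive sampling: favour the new subtree
        if np.log(rng.uniform()) < sub.log_w - log_w:
            theta_cur, lp_cur, g_cur = sub.theta_prop, sub.lp_prop, sub.g_prop
        log_w = np.logaddexp(log_w, sub.log_w)
        depth += 1
        dtheta = theta_p - theta_m
        if dtheta @ (inv_mass * r_m) < 0 or dtheta @ (inv_mass * r_p) < 0:
            break
    accept_stat = sum_accept / max(n_accept, 1)
    return theta_cur, lp_cur, g_cur, accept_stat, n_div, depth


def _initial_step_size(theta, lp, g, logp_grad, inv_mass, rng):
    """Heuristic: double/halve eps until one leapfrog step has accept ~0.5."""
    eps = 1.0
    r = rng.standard_normal(theta.size) / np.sqrt(inv_mass)
    h0 = _hamiltonian(lp, r, inv_mass)
    _, r1, lp1, _ = _leapfrog(theta, r, g, eps, logp_grad, inv_mass)
    h1 = _hamiltonian(lp1, r1, inv_mass) if np.isfinite(lp1) else np.inf
    direction = 1 if (h0 - h1) > np.log(0.5) else -1
    for _ in range(50):
        eps *= 2.0**direction
        _, r1, lp1, _ = _leapfrog(theta, r, g, eps, logp_grad, inv_mass)
        h1 = _hamiltonian(lp1, r1, inv_mass) if np.isfinite(lp1) else np.inf
        if direction == 1 and not ((h0 - h1) > np.log(0.5)):
            break
        if direction == -1 and not ((h0 - h1) < np.log(0.5)):
            break
    return eps


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_treedepth: int = 8,
    target_accept: float = 0.9,
) -> tuple[np.ndarray, NutsStats]:
    """Run one NUTS chain; returns (draws[n_draws, dim], stats)."""
    theta = np.asarray(theta0, dtype=float).copy()
    dim = theta.size
    inv_mass = np.ones(dim)
    lp, g = logp_grad(theta)
    if not np.isfinite(lp):
        raise ValueError("initial point has non-finite log density")

    eps = _initial_step_size(theta, lp, g, logp_grad, inv_mass, rng)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    da_count = 0

    # mass-update checkpoints (fractions of warm-up); dual averaging restarts
    checkpoints = sorted({int(n_warmup * f) for f in (0.3, 0.55, 0.85)} - {0})
    window_draws: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    accepts, depths, n_div = [], [], 0

    for it in range(n_warmup + n_draws):
        theta, lp, g, accept, div, depth = _nuts_step(
            theta, lp, g, eps, logp_grad, inv_mass, rng, max_treedepth
        )
        n_div += div
        if it < n_warmup:
            da_count += 1
            frac = 1.0 / (da_count + t0)
            h_bar = (1 - frac) * h_bar + frac * (target_accept - accept)
            log_eps = mu - np.sqrt(da_count) / gamma * h_bar
            w = da_count ** (-kappa)
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            window_draws.append(theta.copy())
            if (it + 1) in checkpoints and len(window_draws) >= 10:
                var = np.var(np.asarray(window_draws[len(window_draws) // 2:]), axis=0)
                nw = len(window_draws)
                inv_mass = (nw / (nw + 5.0)) * var + (5.0 / (nw + 5.0)) * 1e-3
                inv_mass = np.maximum(inv_mass, 1e-8)
                window_draws = []
                eps = _initial_step_size(theta, lp, g, logp_grad, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar, da_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = theta
            accepts.append(accept)
            depths.append(depth)

    stats = NutsStats(
        step_size=eps,
        mean_accept=float(np.mean(accepts)) if accepts else float("nan"),
        n_divergent=n_div,
        mean_treedepth=float(np.mean(depths)) if depths else float("nan"),
        inv_mass=inv_mass,
    )
    return draws, stats
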