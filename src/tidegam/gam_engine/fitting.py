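"""Posterior sampling for the hierarchical Poisson GAMs.

The joint density is Poisson (log link) in the counts with Gaussian priors on
all coefficients: Normal(0, 2) on intercept and fixed index, penalty-structured
Gaussians on smooth blocks whose scales get Exponential(1) priors (sampled on
the log scale with the Jacobian), and a shared Exponential(1)-scaled Gaussian
on camera intercepts.  Gradients are analytic; sampling is NUTS.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from ..errors import ArgumentError, ModelSpecError
from .model import DesignMatrices, PriorBlock
from .sampler import NutsStats, sample_nuts

RHAT_LIMIT = 1.01


def _scale_index(blocks: Sequence[PriorBlock]) -> list[str]:
    names: list[str] = []
    for b in blocks:
        for s in b.scale_names:
            if s not in names:
                names.append(s)
    return names


def make_logp_grad(
    X: np.ndarray, y: np.ndarray, blocks: Sequence[PriorBlock]
) -> tuple[Callable, Callable, int, list[str]]:
    """Joint log density (up to constants) and gradient, in the non-centered
    parameterization theta = [w-coeffs, log sigma...].

    Penalized blocks are sampled as whitened coordinates z with standard
    normal priors; the model coefficients are beta = V diag(den^-1/2) z where
    den = ridge + sum_j exp(-2 u_j) lam_j is the prior precision spectrum.
    This removes the scale/coefficient funnel that cripples centered
    hierarchical GAM sampling.  Returns (logp_grad, to_beta, n_coef,
    scale_names) where ``to_beta(draws)`` maps sampled draws back to model
    coefficients.
    """
    P = X.shape[1]
    scale_names = _scale_index(blocks)
    sidx = {s: i for i, s in enumerate(scale_names)}
    K = len(scale_names)

    # effective design: penalized blocks rotated into their eigenbasis
    Xeff = np.array(X, dtype=float, copy=True)
    pen_blocks = []
    for b in blocks:
        if b.iid_scale is not None:
            continue
        V, lams, ridge = b.eigen
        if V is not None:
            Xeff[:, b.sl] = X[:, b.sl] @ V
        scale_idx = np.array([sidx[s] for s in b.scale_names])
        pen_blocks.append((b.sl, V, np.asarray(lams), np.asarray(ridge), scale_idx))
    iid_blocks = [(b.sl, b.iid_scale) for b in blocks if b.iid_scale is not None]

    def _dens(u: np.ndarray):
        """Prior precision spectrum per penalized block at scales exp(u)."""
        out = []
        for sl, V, lams, ridge, scale_idx in pen_blocks:
            prec = np.exp(-2.0 * u[scale_idx])
            out.append(ridge + prec @ lams)
        return out

    def logp_grad(theta: np.ndarray):
        w = theta[:P].copy()  # z for penalized blocks, beta for iid blocks
        u = theta[P:]
        if np.any(np.abs(u) > 20):
            return -np.inf, np.zeros_like(theta)
        dens = _dens(u)
        scale_vecs = []
        for (sl, V, lams, ridge, scale_idx), den in zip(pen_blocks, dens):
            sv = 1.0 / np.sqrt(den)
            scale_vecs.append(sv)
            w[sl] = theta[sl] * sv
        eta = Xeff @ w
        with np.errstate(over="ignore"):
            mu = np.exp(eta)
        tot = mu.sum()
        if not np.isfinite(tot):
            return -np.inf, np.zeros_like(theta)
        lp = float(y @ eta - tot)
        gw = Xeff.T @ (y - mu)
        gtheta = np.zeros_like(theta)
        gu = np.zeros(K)
        for (sl, V, lams, ridge, scale_idx), den, sv in zip(
            pen_blocks, dens, scale_vecs
        ):
            z = theta[sl]
            lp += -0.5 * float(z @ z)
            gtheta[sl] = gw[sl] * sv - z
            # d(den^-1/2)/du_j = exp(-2 u_j) lam_j den^-3/2
            core = gw[sl] * z / den * sv  # gw * z * den^-3/2
            prec = np.exp(-2.0 * u[scale_idx])
            for j, si in enumerate(scale_idx):
                gu[si] += prec[j] * float(lams[j] @ core)
        for sl, s in iid_blocks:
            bb = theta[sl]
            lp += -0.5 * float(bb @ bb) / s**2
            gtheta[sl] = gw[sl] - bb / s**2
        # Exponential(1) prior on sigma = e^u, with log-scale Jacobian
        lp += float(u.sum() - np.exp(u).sum())
        gu += 1.0 - np.exp(u)
        gtheta[P:] = gu
        return lp, gtheta

    def to_beta(draws: np.ndarray) -> np.ndarray:
        """Map sampled draws (…, P+K) to model-coefficient draws (…, P)."""
        flat = draws.reshape(-1, P + K)
        beta = flat[:, :P].copy()
        u = flat[:, P:]
        for sl, V, lams, ridge, scale_idx in pen_blocks:
            prec = np.exp(-2.0 * u[:, scale_idx])  # (S, n_pen)
            den = ridge[None, :] + prec @ lams  # (S, m)
            wb = flat[:, sl] / np.sqrt(den)
            beta[:, sl] = wb @ V.T if V is not None else wb
        return beta.reshape(draws.shape[:-1] + (P,))

    return logp_grad, to_beta, P, scale_names


def _prior_precision(blocks: Sequence[PriorBlock], P: int) -> np.ndarray:
    """Full prior precision at all sigma = 1 (used for initialization)."""
    Q = np.zeros((P, P))
    for b in blocks:
        if b.iid_scale is not None:
            Q[b.sl, b.sl] += np.eye(b.size) / b.iid_scale**2
            continue
        V, lams, ridge = b.eigen
        d = ridge + sum(lams)
        Qb = (V * d) @ V.T if V is not None else np.diag(d)
        Q[b.sl, b.sl] += Qb
    return Q


def _irls_init(X: np.ndarray, y: np.ndarray, Q: np.ndarray, n_iter: int = 8) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 0.1))
    for _ in range(n_iter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        H = X.T @ (X * mu[:, None]) + Q
        g = X.T @ (y - mu) - Q @ beta
        try:
            beta = beta + np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
    return beta


@dataclass
class FitResult:
    """Posterior draws with diagnostics.

    ``draws`` has shape (chains, draws_per_chain, dim) where the first
    ``n_coef`` columns are coefficients and the rest are log scale
    parameters.  ``converged`` is False when any Rhat >= 1.01.
    """

    draws: np.ndarray
    param_names: list[str]
    index_map: dict[str, slice]
    scale_names: list[str]
    n_coef: int
    rhat: np.ndarray
    ess_bulk: np.ndarray
    ess_tail: np.ndarray
    converged: bool
    settings: dict
    seed: int
    sampler_stats: list[NutsStats] = field(default_factory=list)
    design: Optional[DesignMatrices] = None

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def beta(self) -> np.ndarray:
        """(total draws, n_coef) coefficient draws."""
        return self.flat[:, : self.n_coef]

    @property
    def sigma(self) -> pd.DataFrame:
        """Posterior draws of the scale parameters (natural scale)."""
        return pd.DataFrame(
            np.exp(self.flat[:, self.n_coef:]), columns=self.scale_names
        )

    def max_rhat(self) -> float:
        return float(np.nanmax(self.rhat))

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "rhat": self.rhat,
                "ess_bulk": self.ess_bulk,
                "ess_tail": self.ess_tail,
            }
        )

    def save(self, directory) -> None:
        """Fit archive: draws matrix, index map, diagnostics CSV, settings."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "draws.npy", self.draws)
        self.diagnostics_frame().to_csv(d / "diagnostics.csv", index=False)
        meta = {
            "index_map": {k: [v.start, v.stop] for k, v in self.index_map.items()},
            "scale_names": self.scale_names,
            "n_coef": self.n_coef,
            "converged": self.converged,
            "settings": self.settings,
            "seed": self.seed,
            "param_names": self.param_names,
        }
        (d / "fit.json").write_text(json.dumps(meta, indent=1))


def _diagnostics(draws: np.ndarray):
    """Per-parameter split-Rhat and bulk/tail ESS via arviz."""
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior={"theta": draws})
        rhat = az.rhat(idata)["theta"].to_numpy()
        ess_b = az.ess(idata, method="bulk")["theta"].to_numpy()
        ess_t = az.ess(idata, method="tail")["theta"].to_numpy()
    return rhat, ess_b, ess_t


def fit(
    design: DesignMatrices,
    *,
    chains: int = 3,
    iterations: int = 4000,
    warmup: int = 2000,
    seed: int = 0,
    max_treedepth: int = 10,
    target_accept: float = 0.9,
) -> FitResult:
    """Sample the posterior of an assembled model.

    ``iterations`` counts warm-up plus retained draws per chain (the retained
    draws are ``iterations - warmup``).  Deterministic given seed+settings.
    """
    return fit_raw(
        design.X,
        design.y,
        design.blocks,
        design.index_map,
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        seed=seed,
        max_treedepth=max_treedepth,
        target_accept=target_accept,
        design=design,
    )


def fit_raw(
    X: np.ndarray,
    y: np.ndarray,
    blocks: Sequence[PriorBlock],
    index_map: Optional[dict] = None,
    *,
    chains: int = 3,
    iterations: int = 4000,
    warmup: int = 2000,
    seed: int = 0,
    max_treedepth: int = 10,
    target_accept: float = 0.9,
    design: Optional[DesignMatrices] = None,
) -> FitResult:
    """Low-level fit on an explicit design matrix and prior blocks."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ArgumentError("design matrix contains non-finite values")
    if np.any(y < 0):
        raise ArgumentError("counts must be non-negative")
    n_keep = iterations - warmup
    if n_keep < 1:
        raise ArgumentError("iterations must exceed warmup")

    logp_grad, to_beta, P, scale_names = make_logp_grad(X, y, blocks)
    K = len(scale_names)
    dim = P + K
    beta0 = _irls_init(X, y, _prior_precision(blocks, P))
    sidx = {s: i for i, s in enumerate(scale_names)}

    all_draws = np.empty((chains, n_keep, dim))
    stats = []
    for c in range(chains):
        rng = np.random.default_rng([seed, c])
        u0 = -0.5 + 0.2 * rng.standard_normal(K)
        theta0 = np.empty(dim)
        theta0[P:] = u0
        theta0[:P] = beta0 + 0.05 * rng.standard_normal(P)
        for b in blocks:  # whiten the penalized blocks' start values
            if b.iid_scale is not None:
                continue
            V, lams, ridge = b.eigen
            prec = np.exp(-2.0 * u0[[sidx[s] for s in b.scale_names]])
            den = ridge + prec @ np.asarray(lams)
            bb = theta0[b.sl]
            bt = V.T @ bb if V is not None else bb
            theta0[b.sl] = bt * np.sqrt(den)
        draws, st = sample_nuts(
            logp_grad,
            theta0,
            n_warmup=warmup,
            n_draws=n_keep,
            rng=rng,
            max_treedepth=max_treedepth,
            target_accept=target_accept,
        )
        all_draws[c] = draws
        stats.append(st)
    # report on the model scale: coefficients beta, log scales u
    all_draws = np.concatenate([to_beta(all_draws), all_draws[:, :, P:]], axis=-1)

    if index_map is None:
        index_map = {"coef": slice(0, P)}
    param_names = _param_names(index_map, P, scale_names)
    rhat, ess_b, ess_t = _diagnostics(all_draws)
    worst = np.nanmax(rhat) if not np.all(np.isnan(rhat)) else np.inf
    converged = bool(worst < RHAT_LIMIT) if chains > 1 else True
    if not converged:
        warnings.warn(
            f"sampler not converged: max Rhat {worst:.3f} >= {RHAT_LIMIT}",
            stacklevel=2,
        )
    return FitResult(
        draws=all_draws,
        param_names=param_names,
        index_map=dict(index_map),
        scale_names=scale_names,
        n_coef=P,
        rhat=rhat,
        ess_bulk=ess_b,
        ess_tail=ess_t,
        converged=converged,
        settings={
            "chains": chains,
            "iterations": iterations,
            "warmup": warmup,
            "max_treedepth": max_treedepth,
            "target_accept": target_accept,
        },
        seed=seed,
        sampler_stats=stats,
        design=design,
    )


def _param_names(index_map: dict, P: int, scale_names: list[str]) -> list[str]:
    names = [""] * P
    for term, sl in index_map.items():
        for j, col in enumerate(range(sl.start, sl.stop)):
            names[col] = f"{term}[{j}]" if sl.stop - sl.start > 1 else term
    return names + list(scale_names)


# ---------------------------------------------------------------------------
# posterior smooth evaluation


def posterior_smooth(
    fit_result: FitResult,
    grid_points,
    level: Optional[str] = None,
    include_global: bool = True,
) -> np.ndarray:
    """Evaluate the fitted tensor smooth at new (t_z, d_z) points for every
    posterior draw: the global surface plus, when ``level`` names a factor
    level, that level's deviation surface.  Link scale; intercept, fixed
    index and camera effects excluded.  Returns (total draws, n_points).
    """
    dm = fit_result.design
    if dm is None:
        raise ModelSpecError("fit has no attached design; cannot evaluate smooths")
    pts = np.asarray(grid_points, dtype=float)
    t, d = pts[:, 0], pts[:, 1]
    lo, hi = dm.d_range
    span = hi - lo
    if np.any(d < lo - 0.05 * span) or np.any(d > hi + 0.05 * span):
        warnings.warn("grid extends beyond 1.05x the observed distance hull",
                      stacklevel=2)
    T = dm.tensor.rows(t, d)
    beta = fit_result.beta
    out = np.zeros((beta.shape[0], pts.shape[0]))
    if include_global:
        out += beta[:, dm.index_map["smooth_global"]] @ T.T
    if level is not None:
        key = f"smooth_{level}"
        if key not in dm.index_map:
            raise ModelSpecError(f"unknown smooth level {level!r}")
        out += beta[:, dm.index_map[key]] @ T.T
    return out


# ---------------------------------------------------------------------------
# prior and posterior predictive


def prior_predictive(
    design: DesignMatrices, n_draws: int = 200, seed: int = 0,
    prior_scale: Optional[float] = None,
) -> dict:
    """Simulate counts from the priors through the log link.

    Returns the simulated counts (n_draws x n rows), the rate quantiles and
    the coefficient draws used.  Rates are capped at 1e6 before Poisson
    simulation (prior tails through exp are heavy; the cap only affects the
    simulated counts, not the reported rate quantiles).
    """
    rng = np.random.default_rng(seed)
    n, P = design.X.shape
    ps = prior_scale if prior_scale is not None else design.spec.prior_scale
    rates = np.empty((n_draws, n))
    counts = np.empty((n_draws, n), dtype=np.int64)
    for s in range(n_draws):
        beta = np.zeros(P)
        sig = {name: rng.exponential(1.0) for name in _scale_index(design.blocks)}
        for b in design.blocks:
            if b.iid_scale is not None:
                beta[b.sl] = rng.normal(0.0, ps, b.size)
                continue
            V, lams, ridge = b.eigen
            den = ridge + sum(
                lam / sig[name] ** 2 for name, lam in zip(b.scale_names, lams)
            )
            bt = rng.standard_normal(b.size) / np.sqrt(den)
            beta[b.sl] = V @ bt if V is not None else bt
        lam = np.exp(np.clip(design.X @ beta, -30, np.log(1e6)))
        rates[s] = lam
        counts[s] = rng.poisson(lam)
    return {
        "counts": counts,
        "rate_quantiles": {
            q: float(np.quantile(rates, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
        },
    }


def posterior_predictive_check(
    fit_result: FitResult, y: Optional[np.ndarray] = None,
    max_draws: int = 200, seed: int = 0,
) -> dict:
    """Replicate counts from posterior draws and compare summary statistics
    (mean, s.d., max) of replicates against the observed counts.

    Tail probability per statistic = fraction of replicates with a value at
    or above the observed one; values near 0 or 1 indicate misfit.
    """
    dm = fit_result.design
    if y is None:
        if dm is None:
            raise ModelSpecError("need observed counts or an attached design")
        y = dm.y
    X = dm.X
    rng = np.random.default_rng(seed)
    beta = fit_result.beta
    take = np.linspace(0, beta.shape[0] - 1, min(max_draws, beta.shape[0])).astype(int)
    stats = {"mean": [], "sd": [], "max": []}
    for i in take:
        lam = np.exp(np.clip(X @ beta[i], -30, 30))
        rep = rng.poisson(lam)
        stats["mean"].append(rep.mean())
        stats["sd"].append(rep.std(ddof=1))
        stats["max"].append(rep.max())
    obs = {"mean": y.mean(), "sd": y.std(ddof=1), "max": y.max()}
    out = {"observed": obs, "replicated": {k: np.asarray(v) for k, v in stats.items()}}
    out["tail_prob"] = {
        k: float(np.mean(out["replicated"][k] >= obs[k])) for k in obs
    }
    return out
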