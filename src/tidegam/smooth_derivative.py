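"""Posterior finite-difference derivative of a 2-D tensor smooth and the
89% sign-consistency reliability criterion.

For each posterior draw the fitted surface f(t, d) is re-evaluated at four
small offsets and combined with the four-point stencil

    [f(t+h, d+k) - f(t+h, d-k) - f(t-h, d+k) + f(t-h, d-k)] / (4 h k),

which approximates the mixed partial d2f/dt dd (the literature using this
stencil on fitted smooths calls it "the first derivative" of the tensor
interaction; the stencil itself is the mixed second partial).  Each draw is
differenced against itself only — the derivative of one surface, never a
mixture across draws.  Offsets default to 0.001 on the z-transformed
predictor scale, i.e. 1/1000th of one standard deviation of each predictor.

A grid cell is *reliable* when at least 89% of the posterior draws of this
derivative share one sign: strong, direction-consistent evidence for a
change in activity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd

from .errors import ArgumentError, PropagationError

DEFAULT_EPS = 0.001
DEFAULT_THRESHOLD = 0.89


@dataclass(frozen=True)
class Grid2D:
    """Rectangular evaluation grid on the z-scale."""

    t_values: np.ndarray
    d_values: np.ndarray

    def __post_init__(self):
        for name in ("t_values", "d_values"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1 or v.size < 1 or np.any(np.diff(v) <= 0):
                raise ArgumentError(f"{name} must be strictly increasing 1-D")
            object.__setattr__(self, name, v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.t_values.size, self.d_values.size

    @property
    def n_cells(self) -> int:
        return self.t_values.size * self.d_values.size

    def points(self) -> np.ndarray:
        """(G, 2) array of (t, d) pairs, t-major order."""
        tt, dd = np.meshgrid(self.t_values, self.d_values, indexing="ij")
        return np.column_stack([tt.ravel(), dd.ravel()])

    @classmethod
    def regular(cls, t_range, d_range, n_t: int = 50, n_d: int = 50) -> "Grid2D":
        return cls(np.linspace(*t_range, n_t), np.linspace(*d_range, n_d))


@dataclass
class DerivativeField:
    """Per-draw mixed-partial values on a grid, with sign proportions."""

    grid: Grid2D
    eps_h: float
    eps_k: float
    draws: np.ndarray  # (S, G)
    mean: np.ndarray = field(init=False)
    prop_pos: np.ndarray = field(init=False)
    prop_neg: np.ndarray = field(init=False)

    def __post_init__(self):
        if self.draws.ndim != 2 or self.draws.shape[1] != self.grid.n_cells:
            raise ArgumentError("draws must be (S, n_cells)")
        if not np.all(np.isfinite(self.draws)):
            bad = np.argwhere(~np.isfinite(self.draws))[0]
            raise PropagationError(
                f"non-finite derivative at draw {bad[0]}, cell {bad[1]}"
            )
        self.mean = self.draws.mean(axis=0)
        self.prop_pos, self.prop_neg = sign_proportions(self)


def sign_proportions(fld: "DerivativeField") -> tuple[np.ndarray, np.ndarray]:
    """Per-cell proportions of strictly positive / strictly negative draws
    (exact zeros count in neither)."""
    if fld.draws.shape[0] < 1:
        raise ArgumentError("field has no draws")
    prop_pos = (fld.draws > 0).mean(axis=0)
    prop_neg = (fld.draws < 0).mean(axis=0)
    return prop_pos, prop_neg


@dataclass
class ReliabilityMask:
    """Cells where the winning sign proportion reaches the threshold."""

    grid: Grid2D
    threshold: float
    flagged: np.ndarray  # bool per cell
    sign: np.ndarray  # '+', '-', or '' per cell


def mixed_partial_fd(
    evaluator: Callable[[np.ndarray, np.ndarray], np.ndarray],
    grid: Grid2D,
    eps_h: float = DEFAULT_EPS,
    eps_k: float = DEFAULT_EPS,
) -> DerivativeField:
    """Four-point finite-difference mixed partial, per posterior draw.

    ``evaluator(t, d)`` takes flat arrays of points and returns an (S, G)
    matrix of smooth values, one row per posterior draw; the stencil is
    applied row-wise so each draw is differenced against itself.
    """
    if eps_h <= 0 or eps_k <= 0:
        raise ArgumentError("offsets eps_h, eps_k must be > 0")
    pts = grid.points()
    t, d = pts[:, 0], pts[:, 1]
    fpp = evaluator(t + eps_h, d + eps_k)
    fpm = evaluator(t + eps_h, d - eps_k)
    fmp = evaluator(t - eps_h, d + eps_k)
    fmm = evaluator(t - eps_h, d - eps_k)
    vals = (fpp - fpm - fmp + fmm) / (4.0 * eps_h * eps_k)
    vals = np.atleast_2d(np.asarray(vals, dtype=float))
    return DerivativeField(grid, eps_h, eps_k, vals)


def reliability_mask(
    field_or_props,
    threshold: float = DEFAULT_THRESHOLD,
    grid: Optional[Grid2D] = None,
) -> ReliabilityMask:
    """Flag cells whose positive or negative sign proportion reaches the
    threshold (default 0.89).  Thresholds at or below 0.5 are rejected: both
    signs could qualify at once."""
    if not (0.5 < threshold <= 1.0):
        raise ArgumentError(f"threshold must be in (0.5, 1], got {threshold}")
    if isinstance(field_or_props, DerivativeField):
        prop_pos, prop_neg = field_or_props.prop_pos, field_or_props.prop_neg
        grid = field_or_props.grid
    else:
        prop_pos, prop_neg = field_or_props
        prop_pos = np.asarray(prop_pos, float)
        prop_neg = np.asarray(prop_neg, float)
        if grid is None:
            grid = Grid2D(np.arange(prop_pos.size, dtype=float) + 0.0, np.array([0.0]))
    pos = prop_pos >= threshold
    neg = prop_neg >= threshold
    sign = np.where(pos, "+", np.where(neg, "-", ""))
    return ReliabilityMask(grid, threshold, pos | neg, sign)


def smooth_evaluator(fit_result, level: Optional[str] = None) -> Callable:
    """Vectorized (t, d) -> (S, G) evaluator of a fitted tensor smooth
    (global + optional level deviation), for use with mixed_partial_fd."""
    from .gam_engine.fitting import posterior_smooth

    def ev(t: np.ndarray, d: np.ndarray) -> np.ndarray:
        pts = np.column_stack([np.asarray(t, float), np.asarray(d, float)])
        return posterior_smooth(fit_result, pts, level=level)

    return ev


def derivative_field(
    fit_result,
    grid: Grid2D,
    level: Optional[str] = None,
    eps_h: float = DEFAULT_EPS,
    eps_k: float = DEFAULT_EPS,
) -> DerivativeField:
    """Mixed-partial field of a fitted smooth on a grid (z-scale)."""
    return mixed_partial_fd(smooth_evaluator(fit_result, level), grid, eps_h, eps_k)


def export_derivative_csv(
    fld: DerivativeField,
    mask: ReliabilityMask,
    path: Union[str, Path],
    t_std=None,
    d_std=None,
) -> pd.DataFrame:
    """Write the per-cell derivative summary; when standardizers are given,
    also report the grid on the raw scale (hours, metres)."""
    pts = fld.grid.points()
    df = pd.DataFrame(
        {
            "t_z": pts[:, 0],
            "d_z": pts[:, 1],
            "t_hours": t_std.inverse(pts[:, 0]) if t_std else np.nan,
            "d_metres": d_std.inverse(pts[:, 1]) if d_std else np.nan,
            "mean_deriv": fld.mean,
            "prop_pos": fld.prop_pos,
            "prop_neg": fld.prop_neg,
            "flagged": mask.flagged,
            "sign": mask.sign,
        }
    )
    df.to_csv(path, index=False)
    return df
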