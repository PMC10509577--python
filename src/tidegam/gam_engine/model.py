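"""Hierarchical Poisson GAM structures.

Five model structures are supported, all Poisson with log link on positive
per-sequence counts:

* ``MT_1`` — time-to-low-tide x distance tensor smooth; global surface plus
  per-group (tool / nontool) deviation surfaces; group index fixed effect
  (tool = 1, nontool = 0); camera random intercepts.
* ``MT_2`` / ``MT_3`` — same structure fit to the tool-using / non-tool-using
  subset, with season (dry / wet) as the deviation factor and fixed index.
* ``MD_1`` / ``MD_2`` — as MT_2/MT_3 but with hour of day replacing time to
  low tide (cyclic on [0, 24) by default, since hour 23 adjoins hour 0).

Priors: Normal(0, 2) on the intercept and fixed index, Exponential(1) on all
scale parameters.  Smooth wiggliness is controlled hierarchically: each
tensor block has one scale per marginal penalty direction, giving the
Gaussian prior precision ``S_t / sigma_t^2 + S_d / sigma_d^2``.  Camera
intercepts share a single Exponential(1)-scaled Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..detections import ModelTable
from ..errors import ModelSpecError
from .splines import TensorSmooth, cubic_basis, cyclic_cubic_basis, tensor_product

MODEL_IDS = ("MT_1", "MT_2", "MT_3", "MD_1", "MD_2")

#: factor / time covariate per model structure
_MODEL_LAYOUT = {
    "MT_1": ("group", "t_z"),
    "MT_2": ("season", "t_z"),
    "MT_3": ("season", "t_z"),
    "MD_1": ("season", "h_z"),
    "MD_2": ("season", "h_z"),
}
#: index coding: level mapped to 1 (the other level is the reference 0)
_INDEX_ONE = {"group": "tool", "season": "wet"}
_FACTOR_LEVELS = {"group": ("tool", "nontool"), "season": ("dry", "wet")}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative structure of one hierarchical GAM."""

    model_id: str = "MT_1"
    k_time: int = 8
    k_dist: int = 8
    cyclic_hour: bool = True
    shared_smooth_scales: bool = False  # one scale pair shared by all tensors
    prior_scale: float = 2.0  # Normal(0, prior_scale) on unpenalized terms

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise ModelSpecError(f"unknown model_id {self.model_id!r}")

    @property
    def factor(self) -> str:
        return _MODEL_LAYOUT[self.model_id][0]

    @property
    def time_var(self) -> str:
        return _MODEL_LAYOUT[self.model_id][1]

    @property
    def levels(self) -> tuple[str, str]:
        return _FACTOR_LEVELS[self.factor]


@dataclass
class PriorBlock:
    """One coefficient block and its Gaussian prior structure.

    ``penalties`` each get their own scale parameter sigma ~ Exponential(1);
    prior precision = sum_j S_j / sigma_j^2, plus a Normal(0, prior_scale)
    ridge on any joint null-space directions so the prior is proper.
    ``iid_scale`` blocks instead use a fixed Normal(0, iid_scale) prior with
    no sampled scale.

    ``eigen`` holds (V, [lam_j...], ridge_diag): an orthogonal V that
    simultaneously diagonalizes every penalty in the block (possible here
    because the two tensor-direction penalties S_t (x) I and I (x) S_d
    commute), the penalty eigenvalues in that basis, and the ridge precision
    per coordinate.  V is None for identity-penalty blocks.
    """

    name: str
    sl: slice
    penalties: list[np.ndarray] = field(default_factory=list)
    scale_names: list[str] = field(default_factory=list)
    eigen: Optional[tuple] = None  # (V | None, list[np.ndarray], np.ndarray)
    iid_scale: Optional[float] = None

    @property
    def size(self) -> int:
        return self.sl.stop - self.sl.start


@dataclass
class DesignMatrices:
    """Assembled design + prior structure, re-evaluable on new points."""

    X: np.ndarray  # n x P dense design (column order documented below)
    y: np.ndarray  # counts
    blocks: list[PriorBlock]
    index_map: dict[str, slice]
    tensor: TensorSmooth  # shared marginal bases for all tensor blocks
    spec: ModelSpec
    levels: tuple[str, str]
    camera_levels: list[str]
    level_of_row: np.ndarray  # factor level per row (strings)
    t_domain: tuple[float, float]  # z-scale cyclic domain of the time margin
    d_range: tuple[float, float]

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    def smooth_rows(self, t_z, d_z, level: Optional[str] = None) -> np.ndarray:
        """Tensor design rows at new (t_z, d_z) points (global block layout;
        deviation blocks share the same basis)."""
        return self.tensor.rows(np.asarray(t_z, float), np.asarray(d_z, float))


def assemble_design(table: ModelTable, spec: ModelSpec) -> DesignMatrices:
    """Build the dense design and prior blocks for one model structure.

    Column order: intercept | factor index | global tensor | one deviation
    tensor per factor level | camera intercepts.
    """
    df = table.data
    if len(df) == 0:
        raise ModelSpecError("empty model table")
    factor = spec.factor
    present = set(df[factor].unique())
    for lev in spec.levels:
        if lev not in present:
            raise ModelSpecError(
                f"level {lev!r} of factor {factor!r} absent from table"
            )

    # marginal bases ---------------------------------------------------
    tvals = df[spec.time_var].to_numpy(float)
    dvals = df["d_z"].to_numpy(float)
    if spec.time_var == "t_z":
        L = table.tide_interval_h
        raw_dom = (-L / 2.0, L / 2.0)
        std = table.t_std
    else:
        raw_dom = (0.0, 24.0)
        std = table.h_std
    # cyclic wrap is defined on the raw scale; the z-transform is affine so
    # the domain maps to z-scale endpoints
    t_dom = (float(std.transform(raw_dom[0])), float(std.transform(raw_dom[1])))
    if spec.time_var == "h_z" and not spec.cyclic_hour:
        bt = cubic_basis(tvals, spec.k_time)
    else:
        bt = cyclic_cubic_basis(tvals, spec.k_time, t_dom)
    bd = cubic_basis(dvals, spec.k_dist)
    tensor = tensor_product(bt, bd)
    m = tensor.n_coef

    # columns ----------------------------------------------------------
    n = len(df)
    cams = sorted(df["camera_id"].unique())
    cam_idx = {c: i for i, c in enumerate(cams)}
    level_of_row = df[factor].to_numpy()
    one_level = _INDEX_ONE[factor]

    cols = [np.ones((n, 1)), (level_of_row == one_level).astype(float)[:, None]]
    index_map: dict[str, slice] = {"intercept": slice(0, 1), f"{factor}_index": slice(1, 2)}
    pos = 2

    cols.append(tensor.design)
    index_map["smooth_global"] = slice(pos, pos + m)
    pos += m
    for lev in spec.levels:
        mask = (level_of_row == lev).astype(float)[:, None]
        cols.append(tensor.design * mask)
        index_map[f"smooth_{lev}"] = slice(pos, pos + m)
        pos += m
    cam_cols = np.zeros((n, len(cams)))
    cam_cols[np.arange(n), [cam_idx[c] for c in df["camera_id"]]] = 1.0
    cols.append(cam_cols)
    index_map["camera"] = slice(pos, pos + len(cams))
    pos += len(cams)

    X = np.concatenate(cols, axis=1)

    # prior blocks -----------------------------------------------------
    # joint eigenbasis of the two tensor penalties (they commute):
    # S_t (x) I has eigenvectors U_t (x) U_d with eigenvalues repeat(lam_t),
    # I (x) S_d the same vectors with tile(lam_d).
    lam_t, U_t = np.linalg.eigh(tensor.b1.penalty)
    lam_d, U_d = np.linalg.eigh(tensor.b2.penalty)
    m2 = tensor.b2.n_coef
    lam_t = np.where(lam_t < 1e-10 * max(lam_t.max(), 1.0), 0.0, lam_t)
    lam_d = np.where(lam_d < 1e-10 * max(lam_d.max(), 1.0), 0.0, lam_d)
    V = np.kron(U_t, U_d)
    lam1 = np.repeat(lam_t, m2)
    lam2 = np.tile(lam_d, tensor.b1.n_coef)
    ridge = np.where(lam1 + lam2 <= 0.0, 1.0 / spec.prior_scale**2, 0.0)

    blocks = [
        PriorBlock("fixed", slice(0, 2), iid_scale=spec.prior_scale),
    ]
    smooth_names = ["smooth_global"] + [f"smooth_{lev}" for lev in spec.levels]
    for name in smooth_names:
        if spec.shared_smooth_scales:
            scale_names = ["sigma_smooth_t", "sigma_smooth_d"]
        else:
            scale_names = [f"sigma_{name}_t", f"sigma_{name}_d"]
        blocks.append(
            PriorBlock(
                name,
                index_map[name],
                penalties=list(tensor.penalties),
                scale_names=scale_names,
                eigen=(V, [lam1, lam2], ridge),
            )
        )
    blocks.append(
        PriorBlock(
            "camera",
            index_map["camera"],
            penalties=[np.eye(len(cams))],
            scale_names=["sigma_camera"],
            eigen=(None, [np.ones(len(cams))], np.zeros(len(cams))),
        )
    )

    return DesignMatrices(
        X=X,
        y=df["count"].to_numpy(float),
        blocks=blocks,
        index_map=index_map,
        tensor=tensor,
        spec=spec,
        levels=spec.levels,
        camera_levels=cams,
        level_of_row=level_of_row,
        t_domain=t_dom,
        d_range=(float(dvals.min()), float(dvals.max())),
    )
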