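"""Penalized cubic regression spline bases and tensor-product smooths.

Both marginals use the value-at-knot parameterization of cubic splines: the
coefficients are the spline's values at the knots, the curve between knots is
the natural interpolating cubic, and the wiggliness penalty is the exact
integral of the squared second derivative, ``B' B^{-1} D`` in the standard
banded-matrix construction.  The cyclic variant identifies the two domain
endpoints, so value, first and second derivative match across the wrap —
required for a covariate like time-to-low-tide, where 6 h after one low
adjoins 6 h before the next.

``k`` always counts coefficients *before* the sum-to-zero constraint; the
constraint removes one, so a k1 x k2 tensor smooth has (k1-1)(k2-1) columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..errors import ArgumentError, DomainError


def _banded_matrices(h: np.ndarray, cyclic: bool) -> tuple[np.ndarray, np.ndarray]:
    """B (maps knot 2nd-derivatives) and D (differences of knot values) such
    that B m = D gamma for the interpolating natural/cyclic cubic spline."""
    if cyclic:
        p = h.size  # number of free knots; h[j] = gap after knot j (wraps)
        B = np.zeros((p, p))
        D = np.zeros((p, p))
        for i in range(p):
            hm, hp_ = h[i - 1], h[i]
            B[i, i] = (hm + hp_) / 3.0
            B[i, (i - 1) % p] += hm / 6.0
            B[i, (i + 1) % p] += hp_ / 6.0
            D[i, i] = -(1.0 / hm + 1.0 / hp_)
            D[i, (i - 1) % p] += 1.0 / hm
            D[i, (i + 1) % p] += 1.0 / hp_
        return B, D
    k = h.size + 1  # number of knots
    B = np.zeros((k - 2, k - 2))
    D = np.zeros((k - 2, k))
    for i in range(k - 2):
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -(1.0 / h[i] + 1.0 / h[i + 1])
        D[i, i + 2] = 1.0 / h[i + 1]
    return B, D


@dataclass
class _CubicKnotBasis:
    """Raw (uncentered) value-at-knot cubic basis; re-evaluable at new x."""

    knots: np.ndarray  # all knots incl. the duplicated endpoint if cyclic
    cyclic: bool
    F: np.ndarray = field(init=False, repr=False)  # knot-value -> knot-m map
    penalty: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        kn = np.asarray(self.knots, dtype=float)
        if np.any(np.diff(kn) <= 0):
            raise ArgumentError("knots must be strictly increasing")
        self.knots = kn
        h = np.diff(kn)
        B, D = _banded_matrices(h, self.cyclic)
        Binv_D = np.linalg.solve(B, D)
        if self.cyclic:
            self.F = Binv_D  # p x p, p = len(knots) - 1 free coefficients
        else:
            k = kn.size
            self.F = np.vstack(
                [np.zeros((1, k)), Binv_D, np.zeros((1, k))]
            )  # natural BC: m_1 = m_k = 0
        self.penalty = D.T @ Binv_D
        self.penalty = 0.5 * (self.penalty + self.penalty.T)  # symmetrize

    @property
    def n_coef(self) -> int:
        return self.knots.size - 1 if self.cyclic else self.knots.size

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def rows(self, x, deriv: int = 0) -> np.ndarray:
        """Design rows mapping knot values -> spline value (deriv=0) or first
        derivative (deriv=1) at x.  Cyclic: x reduced modulo the period.
        Non-cyclic: natural linear extension beyond the knot range."""
        if deriv not in (0, 1):
            raise ArgumentError("deriv must be 0 or 1")
        x = np.atleast_1d(np.asarray(x, dtype=float))
        a, b = self.domain
        if self.cyclic:
            xin = a + np.mod(x - a, b - a)
            return self._rows_inside(xin, deriv)
        xin = np.clip(x, a, b)
        X = self._rows_inside(xin, deriv)
        outside = (x < a) | (x > b)
        if np.any(outside):
            if deriv == 0:  # f(x) = f(edge) + (x - edge) f'(edge)
                X[outside] += (x - xin)[outside, None] * self._rows_inside(
                    xin[outside], 1
                )
            # deriv == 1: slope is constant outside -> edge rows already right
        return X

    def _rows_inside(self, x: np.ndarray, deriv: int) -> np.ndarray:
        kn = self.knots
        p = self.n_coef
        j = np.clip(np.searchsorted(kn, x, side="right") - 1, 0, kn.size - 2)
        x0, x1 = kn[j], kn[j + 1]
        hj = x1 - x0
        if deriv == 0:
            am, ap = (x1 - x) / hj, (x - x0) / hj
            cm = ((x1 - x) ** 3 / hj - hj * (x1 - x)) / 6.0
            cp = ((x - x0) ** 3 / hj - hj * (x - x0)) / 6.0
        else:
            am, ap = -1.0 / hj, 1.0 / hj
            cm = (-3.0 * (x1 - x) ** 2 / hj + hj) / 6.0
            cp = (3.0 * (x - x0) ** 2 / hj - hj) / 6.0
        jl = j % p if self.cyclic else j
        jp = (j + 1) % p if self.cyclic else j + 1
        X = np.zeros((x.size, p))
        rows_idx = np.arange(x.size)
        np.add.at(X, (rows_idx, jl), am)
        np.add.at(X, (rows_idx, jp), ap)
        X += cm[:, None] * self.F[jl, :]
        X += cp[:, None] * self.F[jp, :]
        return X


@dataclass
class SmoothBasis:
    """A centered penalized spline basis evaluated on data.

    ``design`` is the n x (k-1) centered design; ``penalty`` the matching
    second-derivative penalty; ``constraint`` the k x (k-1) sum-to-zero
    transform (columns orthonormal, orthogonal to the data column-mean
    vector) so new covariate values can be mapped into the same coefficient
    space.
    """

    raw: _CubicKnotBasis
    constraint: np.ndarray
    design: np.ndarray
    penalty: np.ndarray

    @property
    def cyclic(self) -> bool:
        return self.raw.cyclic

    @property
    def knots(self) -> np.ndarray:
        return self.raw.knots

    @property
    def n_coef(self) -> int:
        return self.constraint.shape[1]

    def rows(self, x, deriv: int = 0) -> np.ndarray:
        return self.raw.rows(x, deriv=deriv) @ self.constraint


def _center(raw: _CubicKnotBasis, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum-to-zero constraint over the data rows: project out the direction
    of the column means (mgcv-style absorbed identifiability constraint)."""
    c = X.mean(axis=0)
    # orthonormal basis of the null space of c^T
    q, _ = np.linalg.qr(np.column_stack([c / np.linalg.norm(c)]), mode="complete")
    Z = q[:, 1:]
    Xc = X @ Z
    Sc = Z.T @ raw.penalty @ Z
    return Z, Xc, 0.5 * (Sc + Sc.T)


def cyclic_cubic_basis(x, k: int, domain: tuple[float, float]) -> SmoothBasis:
    """Cyclic cubic regression spline with k coefficients (k+1 uniform knots,
    endpoints identified) on ``domain``, sum-to-zero centered."""
    x = np.asarray(x, dtype=float)
    if k < 4:
        raise ArgumentError(f"cyclic basis needs k >= 4, got {k}")
    a, b = float(domain[0]), float(domain[1])
    if np.any(x < a) or np.any(x > b):
        raise DomainError(f"x outside cyclic domain [{a}, {b}]")
    raw = _CubicKnotBasis(np.linspace(a, b, k + 1), cyclic=True)
    X = raw.rows(x)
    Z, Xc, Sc = _center(raw, X)
    return SmoothBasis(raw, Z, Xc, Sc)


def cubic_basis(x, k: int, knots: Optional[np.ndarray] = None) -> SmoothBasis:
    """Natural cubic regression spline with k coefficients, knots at the
    quantiles of x (unless given), sum-to-zero centered."""
    x = np.asarray(x, dtype=float)
    if k < 4:
        raise ArgumentError(f"cubic basis needs k >= 4, got {k}")
    if knots is None:
        knots = np.quantile(x, np.linspace(0, 1, k))
        knots = np.unique(knots)
        if knots.size < k:  # heavy ties: fall back to uniform knots
            knots = np.linspace(x.min(), x.max(), k)
    knots = np.asarray(knots, dtype=float)
    if knots.size != k:
        raise ArgumentError(f"expected {k} knots, got {knots.size}")
    raw = _CubicKnotBasis(knots, cyclic=False)
    X = raw.rows(x)
    Z, Xc, Sc = _center(raw, X)
    return SmoothBasis(raw, Z, Xc, Sc)


@dataclass
class TensorSmooth:
    """Row-wise Kronecker product of two centered marginals.

    Column ordering: index = i * m2 + j for marginal-1 column i and
    marginal-2 column j.  One penalty per marginal direction: S1 (x) I and
    I (x) S2, each positive semidefinite.
    """

    b1: SmoothBasis
    b2: SmoothBasis
    design: np.ndarray
    penalties: list[np.ndarray]

    @property
    def n_coef(self) -> int:
        return self.b1.n_coef * self.b2.n_coef

    def rows(self, x1, x2, deriv1: int = 0, deriv2: int = 0) -> np.ndarray:
        """Tensor design rows at new points (optionally of the marginal
        derivatives, for analytic mixed partials)."""
        R1 = self.b1.rows(x1, deriv=deriv1)
        R2 = self.b2.rows(x2, deriv=deriv2)
        return _row_kron(R1, R2)

    def null_space(self, tol: float = 1e-9) -> np.ndarray:
        """Orthonormal basis of the joint penalty null space (directions no
        penalty touches); empty for cyclic x anything after centering."""
        S = sum(self.penalties)
        w, V = np.linalg.eigh(S)
        return V[:, w < tol * max(w.max(), 1.0)]


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    if B.shape[0] != n:
        raise ArgumentError(f"row mismatch: {n} vs {B.shape[0]}")
    return (A[:, :, None] * B[:, None, :]).reshape(n, A.shape[1] * B.shape[1])


def tensor_product(b1: SmoothBasis, b2: SmoothBasis) -> TensorSmooth:
    design = _row_kron(b1.design, b2.design)
    m1, m2 = b1.n_coef, b2.n_coef
    P1 = np.kron(b1.penalty, np.eye(m2))
    P2 = np.kron(np.eye(m1), b2.penalty)
    return TensorSmooth(b1, b2, design, [P1, P2])
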