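import numpy as np
import pytest

from tidegam.errors import ArgumentError, DomainError, ModelSpecError
from tidegam.gam_engine import (
    ModelSpec,
    assemble_design,
    cubic_basis,
    cyclic_cubic_basis,
    tensor_product,
)

DOMAIN = (-6.25, 6.25)
RNG = np.random.default_rng(2024)


@pytest.fixture(scope="module")
def cyclic8():
    x = RNG.uniform(*DOMAIN, 400)
    return cyclic_cubic_basis(x, 8, DOMAIN)


@pytest.fixture(scope="module")
def cubic8():
    x = RNG.uniform(0, 470, 400)
    return cubic_basis(x, 8)


class TestCyclicBasis:
    def test_endpoint_values_match_for_random_coefficients(self, cyclic8):
        ra = cyclic8.rows([DOMAIN[0]])
        rb = cyclic8.rows([DOMAIN[1]])
        for _ in range(100):
            beta = RNG.normal(size=cyclic8.n_coef)
            assert abs((ra - rb) @ beta) < 1e-10

    def test_endpoint_first_derivative_matches(self, cyclic8):
        da = cyclic8.rows([DOMAIN[0]], deriv=1)
        db = cyclic8.rows([DOMAIN[1] - 1e-9], deriv=1)
        beta = RNG.normal(size=cyclic8.n_coef)
        assert (da - db) @ beta == pytest.approx(0.0, abs=1e-5)

    def test_constant_in_raw_penalty_null_space(self, cyclic8):
        ones = np.ones(cyclic8.raw.n_coef)
        assert ones @ cyclic8.raw.penalty @ ones == pytest.approx(0.0, abs=1e-10)

    def test_penalty_psd_and_symmetric(self, cyclic8):
        S = cyclic8.penalty
        assert np.allclose(S, S.T)
        assert np.linalg.eigvalsh(S).min() > -1e-10

    def test_reproduces_unit_sine_at_k20(self):
        x = np.linspace(*DOMAIN, 500)
        b = cyclic_cubic_basis(x, 20, DOMAIN)
        y = np.sin(2 * np.pi * (x - DOMAIN[0]) / (DOMAIN[1] - DOMAIN[0]))
        coef, *_ = np.linalg.lstsq(b.design, y - y.mean(), rcond=None)
        err = np.abs(b.design @ coef + y.mean() - y).max()
        assert err < 1e-3

    def test_evaluation_wraps_modulo_period(self, cyclic8):
        period = DOMAIN[1] - DOMAIN[0]
        x = np.array([1.3])
        assert np.allclose(cyclic8.rows(x), cyclic8.rows(x + period))

    def test_domain_and_k_errors(self):
        with pytest.raises(DomainError):
            cyclic_cubic_basis([7.0], 8, DOMAIN)
        with pytest.raises(ArgumentError):
            cyclic_cubic_basis([0.0], 3, DOMAIN)


class TestCubicBasis:
    def test_linear_in_raw_penalty_null_space(self, cubic8):
        lin = cubic8.raw.knots
        assert lin @ cubic8.raw.penalty @ lin == pytest.approx(0.0, abs=1e-8)

    def test_column_counts(self, cubic8):
        assert cubic8.raw.n_coef == 8
        assert cubic8.design.shape[1] == 7

    def test_interpolates_square_at_knots(self):
        x = np.linspace(0, 1, 300)
        b = cubic_basis(x, 10, knots=np.linspace(0, 1, 10))
        kn = b.raw.knots
        y = kn**2
        # unpenalized least-squares fit to the knot values; the value-at-knot
        # basis (plus intercept) interpolates any knot data exactly
        X = np.column_stack([np.ones(kn.size), b.rows(kn)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.abs(X @ coef - y).max() < 1e-6

    def test_linear_extension_outside_knots(self, cubic8):
        beta = RNG.normal(size=cubic8.n_coef)
        hi = cubic8.raw.knots[-1]
        f = lambda z: (cubic8.rows([z]) @ beta).item()
        slope_in = (cubic8.rows([hi], deriv=1) @ beta).item()
        assert f(hi + 10.0) == pytest.approx(f(hi) + 10.0 * slope_in, rel=1e-9)


class TestTensorProduct:
    def test_dimension_product(self):
        x = RNG.uniform(0, 1, 50)
        b1 = cubic_basis(x, 5)  # 4 centered columns
        b2 = cubic_basis(RNG.uniform(0, 1, 50), 4)  # 3 centered columns
        ts = tensor_product(b1, b2)
        assert ts.design.shape == (50, 12)
        assert all(P.shape == (12, 12) for P in ts.penalties)

    def test_rows_are_outer_products(self, cyclic8, cubic8):
        ts = tensor_product(cyclic8, cubic8)
        for i in (0, 1, 2):
            expect = np.outer(cyclic8.design[i], cubic8.design[i]).ravel()
            assert np.allclose(ts.design[i], expect)

    def test_penalties_psd(self, cyclic8, cubic8):
        ts = tensor_product(cyclic8, cubic8)
        for P in ts.penalties:
            assert np.allclose(P, P.T)
            assert np.linalg.eigvalsh(P).min() > -1e-8

    def test_additive_in_t_has_zero_d_penalty_raw(self, cyclic8, cubic8):
        # on the raw (uncentered) margins a surface g(t)*1(d) is the
        # coefficient vector c_t (x) ones, and the d-direction penalty
        # (I (x) S_d) annihilates it exactly
        c_t = RNG.normal(size=cyclic8.raw.n_coef)
        ones = np.ones(cubic8.raw.n_coef)
        beta = np.kron(c_t, ones)
        Pd = np.kron(np.eye(cyclic8.raw.n_coef), cubic8.raw.penalty)
        assert beta @ Pd @ beta == pytest.approx(0.0, abs=1e-8)

    def test_row_mismatch_rejected(self):
        b1 = cubic_basis(RNG.uniform(0, 1, 30), 5)
        b2 = cubic_basis(RNG.uniform(0, 1, 40), 5)
        with pytest.raises(ArgumentError):
            tensor_product(b1, b2)


class TestAssembleDesign:
    def test_mt1_column_bookkeeping(self, small_table):
        dm = assemble_design(small_table, ModelSpec("MT_1"))
        n_cam = small_table.data["camera_id"].nunique()
        assert dm.X.shape[1] == 1 + 1 + 49 + 2 * 49 + n_cam

    def test_index_map_partitions_columns(self, small_table):
        dm = assemble_design(small_table, ModelSpec("MT_1"))
        cols = []
        for sl in dm.index_map.values():
            cols.extend(range(sl.start, sl.stop))
        assert sorted(cols) == list(range(dm.X.shape[1]))

    def test_marginal_design_columns_centered(self, small_table):
        dm = assemble_design(small_table, ModelSpec("MT_1"))
        assert np.abs(dm.tensor.b1.design.mean(axis=0)).max() < 1e-8
        assert np.abs(dm.tensor.b2.design.mean(axis=0)).max() < 1e-8

    def test_eigen_reconstructs_penalties(self, small_table):
        dm = assemble_design(small_table, ModelSpec("MT_1"))
        blk = next(b for b in dm.blocks if b.name == "smooth_global")
        V, lams, ridge = blk.eigen
        assert np.allclose(V @ V.T, np.eye(V.shape[0]), atol=1e-8)
        for lam, P in zip(lams, blk.penalties):
            assert np.allclose((V * lam) @ V.T, P, atol=1e-8)

    def test_missing_level_rejected(self, small_table):
        tool_only = small_table.subset(group="tool")
        with pytest.raises(ModelSpecError, match="nontool"):
            assemble_design(tool_only, ModelSpec("MT_1"))

    def test_md_model_uses_hour_margin(self, small_table):
        dm = assemble_design(small_table, ModelSpec("MD_1"))
        assert dm.spec.time_var == "h_z"
        assert dm.tensor.b1.cyclic  # hour of day wraps at midnight

    def test_label_swap_permutes_deviation_blocks(self, small_table):
        # swapping the group labels swaps the two deviation designs exactly
        # and complements the index column; the global block is unchanged
        dm = assemble_design(small_table, ModelSpec("MT_1"))
        swapped_table = small_table.subset()  # copy
        swapped_table.data["group"] = swapped_table.data["group"].map(
            {"tool": "nontool", "nontool": "tool"}
        )
        dm2 = assemble_design(swapped_table, ModelSpec("MT_1"))
        assert np.allclose(
            dm.X[:, dm.index_map["smooth_global"]],
            dm2.X[:, dm2.index_map["smooth_global"]],
        )
        assert np.allclose(
            dm.X[:, dm.index_map["smooth_tool"]],
            dm2.X[:, dm2.index_map["smooth_nontool"]],
        )
        assert np.allclose(
            dm.X[:, dm.index_map["group_index"]],
            1.0 - dm2.X[:, dm2.index_map["group_index"]],
        )
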