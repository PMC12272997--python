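import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mtoscca.data import standardize_block
from mtoscca.exceptions import DegenerateDirectionError, ValidationError
from mtoscca.simulate import SimConfig, generate
from mtoscca.solvers import (
    Hyperparams,
    WeightSet,
    fit_mtoscca,
    fit_mtscca,
    l11_norm,
    l21_norm,
    mtoscca_objective,
    rescale_to_constraint,
    reweight_diag_11,
    reweight_diag_21,
    update_u,
    update_v,
)

from conftest import make_block

_RIDGE = 1e-8  # must match the solver's stabilization constant


# ---------------------------------------------------------------- norms

class TestNorms:
    def test_l21_345_row(self):
        assert l21_norm(np.array([[3.0, 4.0], [0.0, 0.0]])) == 5.0

    def test_l21_identity(self):
        assert l21_norm(np.eye(2)) == 2.0

    def test_l11_simple(self):
        assert l11_norm(np.array([[1.0, -2.0], [3.0, 0.0]])) == 6.0

    def test_l11_zero(self):
        assert l11_norm(np.zeros((3, 2))) == 0.0

    def test_l21_matches_double_loop(self, rng):
        W = rng.standard_normal((4, 3))
        expected = sum(math.sqrt(sum(W[i, j] ** 2 for j in range(3)))
                       for i in range(4))
        assert l21_norm(W) == pytest.approx(expected, abs=1e-12)

    def test_l11_matches_double_loop(self, rng):
        W = rng.standard_normal((5, 2))
        expected = sum(abs(W[i, j]) for i in range(5) for j in range(2))
        assert l11_norm(W) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(arrays(float, (3, 2), elements=st.floats(-1e6, 1e6)))
    def test_norms_nonnegative_and_l11_dominates(self, W):
        assert l21_norm(W) >= 0
        assert l11_norm(W) >= l21_norm(W) - 1e-9 * (1 + l11_norm(W))


# ------------------------------------------------------- reweighting diagonals

class TestReweightDiagonals:
    def test_21_definition(self):
        W = np.array([[1.0, 0.0], [0.0, 2.0]])
        np.testing.assert_allclose(reweight_diag_21(W, 1e-6), [0.5, 0.25])

    def test_21_zero_row_capped(self):
        d = reweight_diag_21(np.zeros((2, 2)), 1e-6)
        np.testing.assert_allclose(d, 1 / (2e-6))
        assert np.all(np.isfinite(d))

    def test_21_majorization_identity(self, rng):
        # with D fixed at W, sum_i ||row_i||^2 d_i recovers ||W||_{2,1} / 2
        W = rng.standard_normal((6, 3)) + 0.5
        d = reweight_diag_21(W, 1e-9)
        quad = float(sum(np.linalg.norm(W[i]) ** 2 * d[i] for i in range(6)))
        assert quad == pytest.approx(l21_norm(W) / 2, rel=1e-10)

    def test_11_definition(self):
        np.testing.assert_allclose(reweight_diag_11(np.array([1.0, -0.5]), 1e-6),
                                   [0.5, 1.0])

    def test_11_zero_capped(self):
        np.testing.assert_allclose(reweight_diag_11(np.zeros(3), 1e-6), 1 / (2e-6))

    def test_11_majorization_identity(self, rng):
        v = rng.standard_normal(8) + 2.0  # all |v_j| > eps
        d = reweight_diag_11(v, 1e-6)
        assert float(v @ (d * v)) == pytest.approx(np.abs(v).sum() / 2, rel=1e-10)

    def test_epsilon_must_be_positive(self):
        with pytest.raises(ValidationError):
            reweight_diag_21(np.ones((2, 2)), 0.0)


# ------------------------------------------------------------ rescaling

class TestRescale:
    def test_halves_when_norm_two(self, rng):
        Z = np.eye(3)
        w = np.array([2.0, 0.0, 0.0])
        np.testing.assert_allclose(rescale_to_constraint(w, Z), [1, 0, 0])

    def test_idempotent_on_unit(self, rng):
        Z = rng.standard_normal((8, 4))
        w = rescale_to_constraint(rng.standard_normal(4), Z)
        np.testing.assert_allclose(rescale_to_constraint(w, Z), w, atol=1e-12)

    def test_postcondition_unit_norm(self, rng):
        Z = rng.standard_normal((10, 5))
        w = rescale_to_constraint(rng.standard_normal(5), Z)
        assert np.linalg.norm(Z @ w) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_direction(self):
        with pytest.raises(DegenerateDirectionError):
            rescale_to_constraint(np.array([1.0, 1.0]), np.zeros((3, 2)))


# -------------------------------------------------- update oracles

def _oracle_system_v(X, Y, u, v_prev, V_prev, hp):
    """Entry-by-entry assembly of the v-update linear system."""
    n, q = Y.shape
    A = np.zeros((q, q))
    for i in range(q):
        for j in range(q):
            A[i, j] = (1 + hp.gamma_v) * sum(Y[s, i] * Y[s, j] for s in range(n))
            A[i, j] += 2 * hp.lambda_v3 * (v_prev[i] * v_prev[j] - (i == j))
        row_norm = math.sqrt(sum(V_prev[i, m] ** 2 for m in range(V_prev.shape[1])))
        A[i, i] += hp.lambda_v1 / (2 * max(row_norm, hp.epsilon))
        A[i, i] += hp.lambda_v2 / (2 * max(abs(v_prev[i]), hp.epsilon))
    tr = abs(sum(A[i, i] for i in range(q)))
    for i in range(q):
        A[i, i] += _RIDGE * (tr / q if tr > 0 else 1.0)
    target = X @ u
    b = np.array([sum(Y[s, i] * target[s] for s in range(n)) for i in range(q)])
    return np.linalg.solve(A, b)


def _oracle_system_u(X, Y, v, u_prev, U_prev, hp):
    n, p = X.shape
    A = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            A[i, j] = (1 + hp.gamma_u) * sum(X[s, i] * X[s, j] for s in range(n))
            A[i, j] += 2 * hp.lambda_u2 * (u_prev[i] * u_prev[j] - (i == j))
        row_norm = math.sqrt(sum(U_prev[i, m] ** 2 for m in range(U_prev.shape[1])))
        A[i, i] += hp.lambda_u1 / (2 * max(row_norm, hp.epsilon))
    tr = abs(sum(A[i, i] for i in range(p)))
    for i in range(p):
        A[i, i] += _RIDGE * (tr / p if tr > 0 else 1.0)
    target = Y @ v
    b = np.array([sum(X[s, i] * target[s] for s in range(n)) for i in range(p)])
    return np.linalg.solve(A, b)


class TestUpdateOracles:
    @pytest.mark.parametrize("seed", range(5))
    def test_update_v_matches_independent_assembly(self, seed):
        rng = np.random.default_rng(seed)
        n, p, q, M = 12, 3, 4, 2
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        u = rng.standard_normal(p)
        V_prev = rng.standard_normal((q, M))
        v_prev = V_prev[:, 0]
        hp = Hyperparams(lambda_v1=0.1, lambda_v2=0.1, lambda_v3=0.1,
                         lambda_u1=0.2, lambda_u2=0.05, gamma_v=0.3)
        got = update_v(X, Y, u, v_prev, V_prev, hp)
        want = _oracle_system_v(X, Y, u, v_prev, V_prev, hp)
        np.testing.assert_allclose(got, want, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_update_u_matches_independent_assembly(self, seed):
        rng = np.random.default_rng(seed)
        n, p, q, M = 12, 5, 6, 2
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, q))
        v = rng.standard_normal(q)
        U_prev = rng.standard_normal((p, M))
        u_prev = U_prev[:, 1]
        hp = Hyperparams(lambda_u1=0.15, lambda_u2=0.07, gamma_u=0.2)
        got = update_u(X, Y, v, u_prev, U_prev, hp)
        want = _oracle_system_u(X, Y, v, u_prev, U_prev, hp)
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_update_v_orthonormal_columns_reduces_to_projection(self, rng):
        n, q = 10, 4
        Q, _ = np.linalg.qr(rng.standard_normal((n, q)))  # Q^T Q = I
        X = rng.standard_normal((n, 3))
        u = rng.standard_normal(3)
        hp = Hyperparams(lambda_v1=0, lambda_v2=0, lambda_v3=0,
                         lambda_u1=0, lambda_u2=0)
        got = update_v(X, Q, u, np.ones(q), np.ones((q, 2)), hp)
        np.testing.assert_allclose(got, Q.T @ (X @ u), atol=1e-6)

    def test_update_v_reduces_to_ols(self, rng):
        n, q = 20, 4
        Y = rng.standard_normal((n, q))
        X = rng.standard_normal((n, 3))
        u = rng.standard_normal(3)
        hp = Hyperparams(lambda_v1=0, lambda_v2=0, lambda_v3=0,
                         lambda_u1=0, lambda_u2=0)
        got = update_v(X, Y, u, np.ones(q), np.ones((q, 2)), hp)
        ols, *_ = np.linalg.lstsq(Y, X @ u, rcond=None)
        np.testing.assert_allclose(got, ols, atol=1e-6)

    def test_update_u_reduces_to_ols(self, rng):
        n, p = 25, 4
        X = rng.standard_normal((n, p))
        Y = rng.standard_normal((n, 6))
        v = rng.standard_normal(6)
        hp = Hyperparams(lambda_v1=0, lambda_v2=0, lambda_v3=0,
                         lambda_u1=0, lambda_u2=0)
        got = update_u(X, Y, v, np.ones(p), np.ones((p, 2)), hp)
        ols, *_ = np.linalg.lstsq(X, Y @ v, rcond=None)
        np.testing.assert_allclose(got, ols, atol=1e-6)


# ------------------------------------------------------------- objective

class TestObjective:
    def test_closed_form_at_zero_weights(self):
        block = make_block(n=10, p=3, q=4, M=2, seed=1)
        hp = Hyperparams(lambda_v1=0, lambda_v2=0, lambda_v3=1.0,
                         lambda_u1=0, lambda_u2=1.0)
        weights = WeightSet(np.zeros((3, 2)), np.zeros((4, 2)))
        # each ||0*0^T - I||_F^2 contributes its dimension: 2 * (4 + 3)
        assert mtoscca_objective(block, weights, hp) == pytest.approx(14.0)

    def test_zero_at_exact_fit(self, rng):
        block = make_block(n=3, p=2, q=3, M=1, seed=2, standardized=False)
        hp = Hyperparams(lambda_v1=0, lambda_v2=0, lambda_v3=0,
                         lambda_u1=0, lambda_u2=0)
        u = rng.standard_normal(2)
        # choose v reproducing X u exactly (square invertible Y)
        v = np.linalg.solve(block.Y[0].values, block.X.values @ u)
        assert mtoscca_objective(block, WeightSet(u[:, None], v[:, None]), hp) \
            == pytest.approx(0.0, abs=1e-18)

    def test_matches_term_by_term_summation(self, rng):
        block = make_block(n=8, p=3, q=4, M=2, seed=3)
        hp = Hyperparams(lambda_v1=0.3, lambda_v2=0.2, lambda_v3=0.15,
                         lambda_u1=0.25, lambda_u2=0.1)
        U = rng.standard_normal((3, 2))
        V = rng.standard_normal((4, 2))
        X = block.X.values
        total = 0.0
        for m in range(2):
            Y = block.Y[m].values
            r = X @ U[:, m] - Y @ V[:, m]
            total += sum(ri ** 2 for ri in r)
            total += hp.lambda_v3 * np.linalg.norm(
                np.outer(V[:, m], V[:, m]) - np.eye(4), "fro") ** 2
            total += hp.lambda_u2 * np.linalg.norm(
                np.outer(U[:, m], U[:, m]) - np.eye(3), "fro") ** 2
        total += hp.lambda_v1 * l21_norm(V) + hp.lambda_v2 * l11_norm(V)
        total += hp.lambda_u1 * l21_norm(U)
        got = mtoscca_objective(block, WeightSet(U, V), hp)
        assert got == pytest.approx(total, rel=1e-10)


# ---------------------------------------------------------------- fitting

MODEST = Hyperparams(lambda_v1=0.01, lambda_v2=0.01, lambda_v3=0.01,
                     lambda_u1=0.01, lambda_u2=0.01, max_iter=50)


class TestFit:
    def test_zero_noise_simulation_high_ccc(self):
        block, _ = generate(SimConfig(n=40, p=10, q=25, noise_sigma=1e-8, seed=5))
        res = fit_mtoscca(block, MODEST)
        assert np.all(np.abs(res.ccc) >= 0.95)

    def test_mtscca_zero_noise_high_ccc(self):
        block, _ = generate(SimConfig(n=40, p=10, q=25, noise_sigma=1e-8, seed=6))
        res = fit_mtscca(block, MODEST)
        assert np.all(np.abs(res.ccc) >= 0.95)

    def test_constraints_at_return(self):
        block = make_block(n=30, p=6, q=8, M=2, seed=7)
        res = fit_mtoscca(block, MODEST)
        for m in range(2):
            assert np.linalg.norm(block.X.values @ res.weights.U[:, m]) \
                == pytest.approx(1.0, abs=1e-8)
            assert np.linalg.norm(block.Y[m].values @ res.weights.V[:, m]) \
                == pytest.approx(1.0, abs=1e-8)

    def test_objective_trace_non_increasing(self):
        block = make_block(n=30, p=6, q=8, M=2, seed=8)
        res = fit_mtoscca(block, MODEST)
        tr = res.objective_trace
        tol = 1e-6 * (1 + abs(tr[0]))
        assert np.all(np.diff(tr) <= tol)

    def test_large_orthogonality_penalty_stable(self):
        block = make_block(n=25, p=5, q=6, M=2, seed=9)
        hp = dataclasses.replace(MODEST, lambda_v3=10.0, lambda_u2=10.0)
        res = fit_mtoscca(block, hp)  # no divergence error
        tr = res.objective_trace
        assert np.all(np.isfinite(tr))
        assert np.all(np.diff(tr) <= 1e-6 * (1 + abs(tr[0])))

    def test_deterministic_bit_for_bit(self):
        block = make_block(n=20, p=4, q=5, M=2, seed=10)
        r1 = fit_mtoscca(block, MODEST, init="ones")
        r2 = fit_mtoscca(block, MODEST, init="ones")
        np.testing.assert_array_equal(r1.weights.U, r2.weights.U)
        np.testing.assert_array_equal(r1.weights.V, r2.weights.V)

    def test_random_init_seeded_deterministic(self):
        block = make_block(n=20, p=4, q=5, M=2, seed=11)
        r1 = fit_mtoscca(block, MODEST, init="random")
        r2 = fit_mtoscca(block, MODEST, init="random")
        np.testing.assert_array_equal(r1.weights.U, r2.weights.U)

    def test_reduction_mtscca_equals_zeroed_mtoscca(self):
        block = make_block(n=20, p=4, q=5, M=2, seed=12)
        hp0 = dataclasses.replace(MODEST, lambda_v3=0.0, lambda_u2=0.0)
        r1 = fit_mtoscca(block, hp0)
        r2 = fit_mtscca(block, MODEST)
        np.testing.assert_array_equal(r1.weights.U, r2.weights.U)
        np.testing.assert_array_equal(r1.weights.V, r2.weights.V)
        np.testing.assert_array_equal(r1.objective_trace, r2.objective_trace)

    def test_ccc_nonnegative_after_sign_fix(self):
        block = make_block(n=25, p=5, q=6, M=2, seed=13)
        res = fit_mtoscca(block, MODEST)
        assert np.all(res.ccc >= 0)

    def test_unstandardized_block_standardized_internally(self):
        raw = make_block(n=20, p=4, q=5, M=2, seed=14, standardized=False)
        std = standardize_block(raw)
        r1 = fit_mtoscca(raw, MODEST)
        r2 = fit_mtoscca(std, MODEST)
        np.testing.assert_array_equal(r1.weights.U, r2.weights.U)

    def test_n_iter_within_budget(self):
        block = make_block(n=15, p=3, q=4, M=1, seed=15)
        hp = dataclasses.replace(MODEST, max_iter=7)
        res = fit_mtoscca(block, hp)
        assert res.n_iter <= 7

    def test_invalid_init_rejected(self, small_block):
        with pytest.raises(ValidationError, match="init"):
            fit_mtoscca(small_block, MODEST, init="zeros")


class TestHyperparams:
    def test_negative_lambda_rejected(self):
        with pytest.raises(ValidationError, match="lambda_v1"):
            Hyperparams(lambda_v1=-0.1)

    def test_bad_epsilon_rejected(self):
        with pytest.raises(ValidationError, match="epsilon"):
            Hyperparams(epsilon=0.0)

    def test_bad_max_iter_rejected(self):
        with pytest.raises(ValidationError, match="max_iter"):
            Hyperparams(max_iter=0)

    def test_without_orthogonality(self):
        hp = Hyperparams(lambda_v3=0.5, lambda_u2=0.7).without_orthogonality()
        assert hp.lambda_v3 == 0.0 and hp.lambda_u2 == 0.0
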