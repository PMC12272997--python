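"""Alternating regularized least-squares solvers for multi-task sparse CCA.

Two fitters are provided:

* :func:`fit_mtoscca` — minimizes, over weight matrices ``U`` (p x M) and
  ``V`` (q x M),

  .. math::

     \\sum_m \\bigl[\\|X u_m - Y_m v_m\\|_2^2
        + \\lambda_{v3}\\|v_m v_m^T - I\\|_F^2
        + \\lambda_{u2}\\|u_m u_m^T - I\\|_F^2\\bigr]
     + \\lambda_{v1}\\|V\\|_{2,1} + \\lambda_{v2}\\|V\\|_{1,1}
     + \\lambda_{u1}\\|U\\|_{2,1}

  subject to ``||X u_m|| = ||Y_m v_m|| = 1`` for every task ``m``.

* :func:`fit_mtscca` — the same machinery with the two orthogonality
  penalties forced to zero (the plain multi-task sparse CCA baseline).

Each sub-problem is a linear solve. The non-smooth sparsity norms are
handled by half-quadratic reweighting diagonals recomputed every sweep, the
rank-one orthogonality gradient is linearized at the previous iterate, and
the unit-score constraints are enforced by explicit rescaling after every
update.

Update derivation note
----------------------
The printed closed-form updates in the source method description contain
typographical inconsistencies (a doubled Gram term and a dimensionally
impossible right-hand side). The updates implemented here come from setting
the gradient of the penalized least-squares objective (with the reweighting
diagonals and the linearized orthogonality factor held fixed) to zero:

    [(1 + gamma) * Z^T Z + lam_row * D_row + lam_elem * D_elem
       + 2 * lam_orth * (w w^T - I)] w_new  =  Z^T (partner score)

which reproduces the intended structure with those terms corrected.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import scipy.linalg

from .data import DataBlock, standardize_block
from .exceptions import (
    DegenerateDirectionError,
    DivergenceError,
    NumericalError,
    ValidationError,
)

__all__ = [
    "Hyperparams",
    "WeightSet",
    "FitResult",
    "l21_norm",
    "l11_norm",
    "reweight_diag_21",
    "reweight_diag_11",
    "update_v",
    "update_u",
    "rescale_to_constraint",
    "mtoscca_objective",
    "fit_mtoscca",
    "fit_mtscca",
]

#: relative ridge added to every system matrix before solving; the Y Gram is
#: singular whenever q > n, so the solve needs this unconditionally.
_RIDGE = 1e-8


@dataclass(frozen=True)
class Hyperparams:
    """Penalty strengths and solver controls.

    ``lambda_v1``/``lambda_u1`` weight the row-wise L2,1 norms, ``lambda_v2``
    the element-wise L1,1 norm, and ``lambda_v3``/``lambda_u2`` the per-column
    orthogonality penalties. ``gamma_v``/``gamma_u`` scale the soft version of
    the unit-score constraints (default 0: the constraints are enforced
    exactly by rescaling instead).
    """

    lambda_v1: float = 0.001
    lambda_v2: float = 0.001
    lambda_v3: float = 0.01
    lambda_u1: float = 0.1
    lambda_u2: float = 0.1
    gamma_u: float = 0.0
    gamma_v: float = 0.0
    epsilon: float = 1e-6
    tol: float = 1e-5
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self):
        for name in ("lambda_v1", "lambda_v2", "lambda_v3", "lambda_u1",
                     "lambda_u2", "gamma_u", "gamma_v"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.epsilon <= 0:
            raise ValidationError(f"epsilon must be > 0, got {self.epsilon}")
        if self.tol <= 0:
            raise ValidationError(f"tol must be > 0, got {self.tol}")
        if self.max_iter < 1:
            raise ValidationError(f"max_iter must be >= 1, got {self.max_iter}")

    def without_orthogonality(self) -> "Hyperparams":
        return dataclasses.replace(self, lambda_v3=0.0, lambda_u2=0.0)


@dataclass(frozen=True)
class WeightSet:
    """Canonical weight matrices: U is p x M, V is q x M (columns per task)."""

    U: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        U = np.asarray(self.U, dtype=float)
        V = np.asarray(self.V, dtype=float)
        if U.ndim != 2 or V.ndim != 2:
            raise ValidationError("U and V must be 2-D")
        if U.shape[1] != V.shape[1]:
            raise ValidationError(
                f"U and V must share a task count, got {U.shape[1]} vs {V.shape[1]}"
            )
        if not (np.all(np.isfinite(U)) and np.all(np.isfinite(V))):
            raise ValidationError("non-finite weight entries")
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "V", V)

    @property
    def M(self) -> int:
        return self.U.shape[1]


@dataclass(frozen=True)
class FitResult:
    weights: WeightSet
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    ccc: np.ndarray  # per-task Pearson correlation of the fitted scores


def l21_norm(W: np.ndarray) -> float:
    """Sum over rows of the Euclidean norm of each row."""
    return float(np.linalg.norm(np.atleast_2d(W), axis=1).sum())


def l11_norm(W: np.ndarray) -> float:
    """Sum of absolute values of all entries."""
    return float(np.abs(W).sum())


def reweight_diag_21(W: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Half-quadratic reweighting diagonal for the L2,1 norm.

    Entry i is ``1 / (2 * max(||W[i, :]||, epsilon))``; with this diagonal
    held fixed, ``trace(W^T D W)`` majorizes ``||W||_{2,1} / 2`` at the
    expansion point.
    """
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    norms = np.linalg.norm(np.atleast_2d(W), axis=1)
    return 1.0 / (2.0 * np.maximum(norms, epsilon))


def reweight_diag_11(v: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Reweighting diagonal for the L1 norm: ``1 / (2 * max(|v_j|, epsilon))``."""
    if epsilon <= 0:
        raise ValidationError("epsilon must be > 0")
    return 1.0 / (2.0 * np.maximum(np.abs(np.asarray(v, dtype=float)), epsilon))


def rescale_to_constraint(w: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Return ``w / ||Z w||`` so that the projected score has unit norm."""
    nrm = float(np.linalg.norm(Z @ w))
    if nrm < 1e-12:
        raise DegenerateDirectionError(
            f"projected score norm {nrm:.2e} below 1e-12; weight direction is degenerate"
        )
    return np.asarray(w, dtype=float) / nrm


def _solve_system(gram: np.ndarray, rhs: np.ndarray, row_diag: np.ndarray,
                  elem_diag: Optional[np.ndarray], lam_row: float,
                  lam_elem: float, lam_orth: float, w_prev: np.ndarray,
                  gamma: float) -> np.ndarray:
    """Assemble and solve one regularized stationarity system (see module note)."""
    d = gram.shape[0]
    A = (1.0 + gamma) * gram
    diag = lam_row * row_diag
    if elem_diag is not None:
        diag = diag + lam_elem * elem_diag
    if lam_orth > 0:
        A = A + 2.0 * lam_orth * np.outer(w_prev, w_prev)
        diag = diag - 2.0 * lam_orth
    A = 0.5 * (A + A.T)  # guard against asymmetric round-off
    A[np.diag_indices(d)] += diag
    tr = abs(float(np.trace(A)))
    A[np.diag_indices(d)] += _RIDGE * (tr / d if tr > 0 else 1.0)
    try:
        w = scipy.linalg.solve(A, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise NumericalError(
            f"singular system after stabilization (cond ~ {np.linalg.cond(A):.2e})"
        ) from exc
    if not np.all(np.isfinite(w)):
        raise NumericalError(
            f"non-finite solution (cond ~ {np.linalg.cond(A):.2e})"
        )
    return w


def update_v(X: np.ndarray, Y_m: np.ndarray, u_m: np.ndarray,
             v_prev: np.ndarray, V_prev: np.ndarray, hp: Hyperparams,
             gram: Optional[np.ndarray] = None) -> np.ndarray:
    """One closed-form update of the genetic weight vector for task m.

    Solves ``[(1+gamma_v) Y^T Y + lam_v1 D_21(V_prev) + lam_v2 D_11(v_prev)
    + 2 lam_v3 (v_prev v_prev^T - I)] v = Y^T X u_m``, with symmetrization
    and a relative ridge of 1e-8 for stability (q may exceed n).
    """
    if gram is None:
        gram = Y_m.T @ Y_m
    rhs = Y_m.T @ (X @ u_m)
    return _solve_system(gram, rhs,
                         row_diag=reweight_diag_21(V_prev, hp.epsilon),
                         elem_diag=reweight_diag_11(v_prev, hp.epsilon),
                         lam_row=hp.lambda_v1, lam_elem=hp.lambda_v2,
                         lam_orth=hp.lambda_v3, w_prev=v_prev,
                         gamma=hp.gamma_v)


def update_u(X: np.ndarray, Y_m: np.ndarray, v_m: np.ndarray,
             u_prev: np.ndarray, U_prev: np.ndarray, hp: Hyperparams,
             gram: Optional[np.ndarray] = None) -> np.ndarray:
    """One closed-form update of the imaging weight vector for task m.

    Solves ``[(1+gamma_u) X^T X + lam_u1 D_21(U_prev)
    + 2 lam_u2 (u_prev u_prev^T - I)] u = X^T Y_m v_m``.
    """
    if gram is None:
        gram = X.T @ X
    rhs = X.T @ (Y_m @ v_m)
    return _solve_system(gram, rhs,
                         row_diag=reweight_diag_21(U_prev, hp.epsilon),
                         elem_diag=None,
                         lam_row=hp.lambda_u1, lam_elem=0.0,
                         lam_orth=hp.lambda_u2, w_prev=u_prev,
                         gamma=hp.gamma_u)


def _objective_arrays(X: np.ndarray, Ys, U: np.ndarray, V: np.ndarray,
                      hp: Hyperparams) -> float:
    total = 0.0
    for m, Y in enumerate(Ys):
        u, v = U[:, m], V[:, m]
        r = X @ u - Y @ v
        total += float(r @ r)
        if hp.lambda_v3 > 0:
            q = v.size
            vv = float(v @ v)
            total += hp.lambda_v3 * (vv * vv - 2.0 * vv + q)  # ||v v^T - I||_F^2
        if hp.lambda_u2 > 0:
            p = u.size
            uu = float(u @ u)
            total += hp.lambda_u2 * (uu * uu - 2.0 * uu + p)
    total += hp.lambda_v1 * l21_norm(V) + hp.lambda_v2 * l11_norm(V)
    total += hp.lambda_u1 * l21_norm(U)
    return total


def mtoscca_objective(block: DataBlock, weights: WeightSet,
                      hp: Hyperparams) -> float:
    """Full penalized objective value at the given weights."""
    Ys = [y.values for y in block.Y]
    return _objective_arrays(block.X.values, Ys, weights.U, weights.V, hp)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return np.nan
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def _init_weights(p: int, q: int, M: int, X, Ys, init: str, seed: int):
    if init == "ones":
        U0 = np.ones((p, M))
        V0 = np.ones((q, M))
    elif init == "random":
        rng = np.random.default_rng(seed)
        U0 = rng.standard_normal((p, M))
        V0 = rng.standard_normal((q, M))
    else:
        raise ValidationError(f"init must be 'ones' or 'random', got {init!r}")
    for m in range(M):
        U0[:, m] = rescale_to_constraint(U0[:, m], X)
        V0[:, m] = rescale_to_constraint(V0[:, m], Ys[m])
    return U0, V0


def fit_mtoscca(block: DataBlock, hp: Hyperparams = Hyperparams(),
                init: str = "ones") -> FitResult:
    """Fit the orthogonality-penalized multi-task sparse CCA model.

    Standardizes the block if needed, then alternates per task: v-update and
    rescale, u-update and rescale. Reweighting diagonals are recomputed from
    the current iterate every sweep. Stops when the largest absolute weight
    change over a sweep falls below ``hp.tol``, when ``hp.max_iter`` is
    reached, or when a sweep would increase the objective (that sweep is
    rolled back, keeping the recorded trace non-increasing). Signs are fixed
    at return so every per-task score correlation is >= 0.
    """
    if not block.standardized:
        block = standardize_block(block)
    X = block.X.values
    Ys = [y.values for y in block.Y]
    M = block.M
    p, q = X.shape[1], Ys[0].shape[1]

    U, V = _init_weights(p, q, M, X, Ys, init, hp.seed)
    gram_x = X.T @ X
    gram_y = [Y.T @ Y for Y in Ys]

    trace: List[float] = [_objective_arrays(X, Ys, U, V, hp)]
    converged = False
    n_iter = 0
    for n_iter in range(1, hp.max_iter + 1):
        U_old = U.copy()
        V_old = V.copy()
        for m in range(M):
            v = update_v(X, Ys[m], U[:, m], V[:, m], V, hp, gram=gram_y[m])
            V[:, m] = rescale_to_constraint(v, Ys[m])
            u = update_u(X, Ys[m], V[:, m], U[:, m], U, hp, gram=gram_x)
            U[:, m] = rescale_to_constraint(u, X)
        obj = _objective_arrays(X, Ys, U, V, hp)
        if not np.isfinite(obj):
            raise DivergenceError(
                "objective became non-finite; try smaller lambda_v3/lambda_u2"
            )
        if obj > trace[-1] + 1e-6 * (1.0 + abs(trace[0])):
            # descent safeguard: the linearized orthogonality step can
            # overshoot for large penalties — keep the previous iterate
            U, V = U_old, V_old
            break
        trace.append(obj)
        delta = max(np.abs(U - U_old).max(), np.abs(V - V_old).max())
        if delta < hp.tol:
            converged = True
            break

    ccc = np.empty(M)
    for m in range(M):
        r = _pearson(X @ U[:, m], Ys[m] @ V[:, m])
        if r < 0:  # sign indeterminacy: flip the genetic column of this task
            V[:, m] = -V[:, m]
            r = -r
        ccc[m] = r
    return FitResult(WeightSet(U, V), np.asarray(trace), n_iter, converged, ccc)


def fit_mtscca(block: DataBlock, hp: Hyperparams = Hyperparams(),
               init: str = "ones") -> FitResult:
    """Fit the baseline multi-task sparse CCA (no orthogonality penalties).

    Identical alternating machinery with ``lambda_v3 = lambda_u2 = 0``.
    """
    return fit_mtoscca(block, hp.without_orthogonality(), init=init)
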