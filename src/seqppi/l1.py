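"""Weighted stable l1-minimization (basis pursuit denoising).

Solves

    minimize    sum_i w_i |alpha_i|
    subject to  ||y - X alpha||_2 <= epsilon

by the change of variables beta_i = w_i alpha_i, which turns the problem
into unweighted basis pursuit denoising against the column-rescaled
matrix A = X diag(1/w).  The unweighted problem is solved exactly with a
LASSO homotopy (LARS) path: the regularization parameter is driven from
its maximal value towards zero while the active set is tracked, and the
path is stopped at the exact point where the residual norm crosses
epsilon.  Because the path is piecewise linear, that stopping point is
the exact optimum of the constrained problem, not an iterative
approximation.

If epsilon is smaller than the best residual any coefficient vector can
achieve (the distance from y to the column space of X), the constraint
is infeasible; the minimum-residual least-norm solution is returned with
``converged=False`` and a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

_STEP_TOL = 1e-13
_FEAS_TOL = 1e-9


@dataclass(frozen=True)
class SparseSolution:
    """Outcome of one weighted l1 solve.

    ``objective`` is the weighted l1 norm ``sum_i w_i |alpha_i|``.
    When ``converged`` is False the constraint was infeasible and
    ``alpha`` is the minimum-residual least-norm solution instead.
    """

    alpha: np.ndarray
    converged: bool
    residual_norm: float
    objective: float
    n_iter: int


def _lars_path(A: np.ndarray, y: np.ndarray, epsilon: float, max_iter: int):
    """Run the homotopy path for min ||beta||_1 s.t. ||y - A beta|| <= eps.

    Assumes feasibility was established by the caller.  Returns
    (beta, residual_norm, n_iter, hit) where ``hit`` reports whether the
    epsilon boundary (or an exact representation inside it) was reached.
    """
    m, n = A.shape
    beta = np.zeros(n)
    r = y.copy()
    c = A.T @ r
    lam = float(np.max(np.abs(c)))
    if lam <= _STEP_TOL:  # y (numerically) orthogonal to every column
        return beta, float(np.linalg.norm(r)), 0, np.linalg.norm(r) <= epsilon + _FEAS_TOL
    j0 = int(np.argmax(np.abs(c)))
    active: list[int] = [j0]
    signs: list[float] = [float(np.sign(c[j0]))]

    for it in range(1, max_iter + 1):
        A_act = A[:, active]
        s = np.asarray(signs)
        G = A_act.T @ A_act
        try:
            d = np.linalg.solve(G, s)
        except np.linalg.LinAlgError:
            d = np.linalg.lstsq(G, s, rcond=None)[0]
        v = A_act @ d

        # Candidate steps gamma (lambda decreases by gamma along the segment).
        gamma_max = lam
        step = gamma_max
        event = "zero"
        event_idx = -1

        inactive = np.setdiff1d(np.arange(n), active, assume_unique=False)
        if inactive.size:
            g = A[:, inactive].T @ v
            cj = c[inactive]
            with np.errstate(divide="ignore", invalid="ignore"):
                gp = (lam - cj) / (1.0 - g)
                gm = (lam + cj) / (1.0 + g)
            for arr in (gp, gm):
                valid = np.isfinite(arr) & (arr > _STEP_TOL) & (arr < step - _STEP_TOL)
                if np.any(arr[valid].size and valid):
                    k = int(np.argmin(np.where(valid, arr, np.inf)))
                    if arr[k] < step - _STEP_TOL:
                        step = float(arr[k])
                        event = "enter"
                        event_idx = int(inactive[k])

        b_act = beta[active]
        with np.errstate(divide="ignore", invalid="ignore"):
            gl = -b_act / d
        valid = np.isfinite(gl) & (gl > _STEP_TOL) & (gl < step - _STEP_TOL)
        if np.any(valid):
            k = int(np.argmin(np.where(valid, gl, np.inf)))
            step = float(gl[k])
            event = "leave"
            event_idx = k

        # Does the residual norm cross epsilon inside this segment?
        # ||r - gamma v||^2 = eps^2  is quadratic in gamma.
        a2 = float(v @ v)
        b2 = float(r @ v)
        c2 = float(r @ r) - epsilon * epsilon
        if c2 <= 0.0:  # already inside the ball (can happen on re-entry)
            return beta, float(np.linalg.norm(r)), it, True
        gamma_eps = np.inf
        if a2 > 0.0:
            disc = b2 * b2 - a2 * c2
            if disc >= 0.0:
                root = (b2 - np.sqrt(disc)) / a2  # first (smallest) crossing
                if root > 0.0:
                    gamma_eps = root
        if gamma_eps <= step + _STEP_TOL:
            beta[active] = b_act + gamma_eps * d
            r = r - gamma_eps * v
            return beta, float(np.linalg.norm(r)), it, True

        beta[active] = b_act + step * d
        r = r - step * v
        lam -= step
        c = A.T @ r

        if event == "enter":
            active.append(event_idx)
            signs.append(float(np.sign(c[event_idx])) or 1.0)
        elif event == "leave":
            beta[active[event_idx]] = 0.0
            del active[event_idx]
            del signs[event_idx]
            if not active:
                # Restart from the current residual (rare, degenerate).
                c = A.T @ r
                lam = float(np.max(np.abs(c)))
                if lam <= _STEP_TOL:
                    break
                j0 = int(np.argmax(np.abs(c)))
                active = [j0]
                signs = [float(np.sign(c[j0]))]
        else:  # lambda reached zero: exact representation on the active set
            resid = float(np.linalg.norm(r))
            return beta, resid, it, resid <= epsilon + _FEAS_TOL

    return beta, float(np.linalg.norm(r)), max_iter, False


def solve_weighted_l1(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    epsilon: float,
    max_iter: int = 5000,
    least_squares: Callable[[np.ndarray], np.ndarray] | None = None,
) -> SparseSolution:
    """Solve min sum w_i |alpha_i| s.t. ||y - X alpha|| <= epsilon.

    Parameters
    ----------
    X
        m x n matrix whose columns are (typically unit-norm) atoms.
    weights
        Strictly positive per-atom l1 penalties.
    epsilon
        Reconstruction tolerance; must be positive.
    least_squares
        Optional callable returning the least-norm least-squares solution
        of ``X alpha = y``; used for the feasibility check and the
        infeasible fallback.  Callers solving many right-hand sides
        against one X pass a cached factorization here.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
        raise ValueError("weights must be strictly positive and finite")
    if X.shape[0] != y.size or X.shape[1] != weights.size:
        raise ValueError("shape mismatch between X, y and weights")

    if np.linalg.norm(y) <= epsilon:
        return SparseSolution(np.zeros(X.shape[1]), True, float(np.linalg.norm(y)), 0.0, 0)

    if least_squares is None:
        least_squares = lambda rhs: np.linalg.lstsq(X, rhs, rcond=None)[0]  # noqa: E731
    alpha_ls = least_squares(y)
    r_min = float(np.linalg.norm(y - X @ alpha_ls))
    if r_min > epsilon + _FEAS_TOL:
        warnings.warn(
            f"epsilon={epsilon:g} is below the best achievable residual "
            f"{r_min:g}; returning the minimum-residual least-norm solution",
            RuntimeWarning,
            stacklevel=2,
        )
        objective = float(np.sum(weights * np.abs(alpha_ls)))
        return SparseSolution(alpha_ls, False, r_min, objective, 0)

    A = X / weights
    beta, resid, n_iter, hit = _lars_path(A, y, epsilon, max_iter)
    alpha = beta / weights
    if not hit:
        warnings.warn(
            f"homotopy path did not reach the epsilon boundary in {max_iter} steps",
            RuntimeWarning,
            stacklevel=2,
        )
    return SparseSolution(alpha, hit, resid, float(np.abs(beta).sum()), n_iter)
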