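"""Independent reference implementations used only by the test suite.

Each oracle recomputes a quantity by a route independent of the package
code it checks: the DCT by literal double summation, the weighted l1
problem by general-purpose nonlinear programming, AUC by exhaustive
pair counting, and class residuals by direct least-squares algebra.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def dct2_bruteforce(signal: np.ndarray) -> np.ndarray:
    """Literal O(M^2 N^2) evaluation of the orthonormal 2-D DCT-II.

    out[i, j] = k_i k_j sum_m sum_n x[m, n]
                cos(pi (2m+1) i / (2M)) cos(pi (2n+1) j / (2N))
    with k_0 = sqrt(1/M) and k_i = sqrt(2/M) otherwise (same for N).
    """
    x = np.asarray(signal, dtype=float)
    M, N = x.shape
    out = np.empty((M, N))
    ki = np.full(M, np.sqrt(2.0 / M))
    ki[0] = np.sqrt(1.0 / M)
    kj = np.full(N, np.sqrt(2.0 / N))
    kj[0] = np.sqrt(1.0 / N)
    m = np.arange(M)
    n = np.arange(N)
    for i in range(M):
        ci = np.cos(np.pi * (2 * m + 1) * i / (2 * M))
        for j in range(N):
            cj = np.cos(np.pi * (2 * n + 1) * j / (2 * N))
            out[i, j] = ki[i] * kj[j] * float(ci @ x @ cj)
    return out


def weighted_l1_nlp(X: np.ndarray, y: np.ndarray, weights: np.ndarray,
                    epsilon: float) -> tuple[np.ndarray, float]:
    """Solve min sum w|alpha| s.t. ||y - X alpha|| <= eps by SLSQP.

    Uses the classic split alpha = p - q with p, q >= 0, which makes the
    objective linear and the constraint smooth.  Returns (alpha,
    objective).  Intended for tiny instances only.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = X.shape[1]
    ww = np.concatenate([w, w])

    def constraint(z):
        a = z[:n] - z[n:]
        return epsilon**2 - float(np.sum((y - X @ a) ** 2))

    def constraint_jac(z):
        a = z[:n] - z[n:]
        g = 2.0 * X.T @ (y - X @ a)
        return np.concatenate([g, -g])

    # start from the (feasible) least-squares solution
    a0 = np.linalg.lstsq(X, y, rcond=None)[0]
    z0 = np.concatenate([np.maximum(a0, 0.0), np.maximum(-a0, 0.0)])
    best = None
    for start in (z0, np.zeros(2 * n)):
        res = minimize(
            lambda z: float(ww @ z),
            start,
            jac=lambda z: ww,
            method="SLSQP",
            bounds=[(0.0, None)] * (2 * n),
            constraints=[{"type": "ineq", "fun": constraint, "jac": constraint_jac}],
            options={"maxiter": 5000, "ftol": 1e-12},
        )
        # status 8 ("positive directional derivative") at a feasible point
        # means no descent direction exists, i.e. the optimum was reached
        stalled_at_optimum = "directional derivative" in str(res.message)
        if (res.success or stalled_at_optimum) and constraint(res.x) > -1e-9:
            if best is None or float(ww @ res.x) < float(ww @ best):
                best = res.x
    if best is None:
        raise RuntimeError("oracle failed to converge from both starts")
    alpha = best[:n] - best[n:]
    objective = float(w @ (best[:n] + best[n:]))
    return alpha, objective


def auc_pair_counting(labels, scores) -> float:
    """AUC as the fraction of correctly ordered positive-negative pairs.

    Ties in score contribute one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = len(pos) * len(neg)
    if total == 0:
        raise ValueError("need both classes")
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / total


def src_reference_predict(X: np.ndarray, labels: np.ndarray, y: np.ndarray,
                          epsilon: float) -> int:
    """Unweighted sparse-representation classification via the NLP oracle.

    Normalizes y, solves the unweighted stable l1 problem, masks the
    coefficients per class and returns the argmin-residual class (ties
    to the smaller label).
    """
    yn = y / np.linalg.norm(y)
    alpha, _ = weighted_l1_nlp(X, yn, np.ones(X.shape[1]), epsilon)
    classes = np.unique(labels)
    residuals = [
        float(np.linalg.norm(yn - X @ np.where(labels == c, alpha, 0.0))) for c in classes
    ]
    return int(classes[int(np.argmin(residuals))])
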