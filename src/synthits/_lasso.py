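"""Gram-matrix coordinate-descent lasso used by the synthetic-control fit.

Solves min_b (1/2n)||y - X b||^2 + lam * ||b||_1 with no intercept (callers
center X and y; the intercept is recovered from the training means). Exact
coordinate minimization, so the penalized objective is non-increasing across
updates; sweeps run over columns in input order. lam = 0 falls back to the
least-squares solution computed directly. The hot loop is numba-compiled; a
pure-Python twin exists to record the objective trace for diagnostics.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def soft_threshold(z: float, t: float) -> float:
    return np.sign(z) * max(abs(z) - t, 0.0)


@njit(cache=True)
def _cd_kernel(G: np.ndarray, c: np.ndarray, beta: np.ndarray,
               lam: float, tol: float, max_iter: int) -> None:
    p = len(c)
    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            gjj = G[j, j]
            if gjj <= 0.0:
                beta[j] = 0.0
                continue
            rho = c[j] - np.dot(G[j], beta) + gjj * beta[j]
            if rho > lam:
                new = (rho - lam) / gjj
            elif rho < -lam:
                new = (rho + lam) / gjj
            else:
                new = 0.0
            delta = abs(new - beta[j])
            if delta > max_delta:
                max_delta = delta
            beta[j] = new
        if max_delta < tol:
            break


def lasso_cd(X: np.ndarray, y: np.ndarray, lam: float,
             beta0: np.ndarray | None = None, tol: float = 1e-7,
             max_iter: int = 10_000,
             objective_trace: list | None = None) -> np.ndarray:
    """Coordinate-descent solution of the lasso on centered data.

    ``objective_trace``, if given, is appended with the penalized objective
    after every coordinate update (used to verify monotone descent).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0.0:
        return np.linalg.lstsq(X, y, rcond=None)[0]

    G = X.T @ X / n                      # p x p Gram
    c = X.T @ y / n
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    if objective_trace is None:
        _cd_kernel(G, c, beta, lam, tol, max_iter)
        return beta

    # instrumented pure-Python path
    diag = np.diag(G)

    def objective(b: np.ndarray) -> float:
        r = y - X @ b
        return 0.5 * float(r @ r) / n + lam * float(np.abs(b).sum())

    for _ in range(max_iter):
        max_delta = 0.0
        for j in range(p):
            if diag[j] <= 0:
                beta[j] = 0.0
                continue
            rho = c[j] - G[j] @ beta + diag[j] * beta[j]
            new = soft_threshold(rho, lam) / diag[j]
            max_delta = max(max_delta, abs(new - beta[j]))
            beta[j] = new
            objective_trace.append(objective(beta))
        if max_delta < tol:
            break
    return beta


def lasso_path(X: np.ndarray, y: np.ndarray, lams: np.ndarray,
               tol: float = 1e-7) -> np.ndarray:
    """Warm-started solutions along a descending lambda grid.

    Returns an array of shape (len(lams), p).
    """
    lams = np.asarray(lams, dtype=float)
    if len(lams) > 1 and (np.diff(lams) > 0).any():
        raise ValueError("lambda grid must be non-increasing")
    p = X.shape[1]
    out = np.empty((len(lams), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lams):
        beta = lasso_cd(X, y, lam, beta0=beta, tol=tol)
        out[i] = beta
    return out
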