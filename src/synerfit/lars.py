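"""Least angle regression: variable entry order and coefficient path.

Implements the standard LARS recursion (equiangular direction updates): at
each step the predictor most correlated with the residual joins the active
set, coefficients move along the direction equiangular to all active
predictors, and the step length is the smallest positive gamma at which an
inactive predictor ties the active correlation.  Only the entry order and
the piecewise-linear coefficient path are produced (no lasso modification).

Ties in the entering correlation are broken by the smallest column index so
the path is fully deterministic.  Predictors exactly collinear with the
active set can never enter; the path then stops early, so its length may be
less than the number of columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LarsPath", "lars_order"]

_EPS = 1e-10


@dataclass
class LarsPath:
    entry_order: list[int]          # term indices in order of entry
    coefficient_path: np.ndarray    # (n_steps + 1) x m, row 0 all zeros


def lars_order(X: np.ndarray, y: np.ndarray) -> LarsPath:
    """Run LARS on standardized columns of ``X`` against ``y``.

    ``X`` is expected column-standardized (the algorithm is scale-sensitive);
    zero-variance columns are rejected.  Returns the entry order and the
    coefficient vector after each step.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if n != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if n < 2:
        raise ValueError("need at least 2 rows")
    norms = np.linalg.norm(X - X.mean(axis=0), axis=0)
    if np.any(norms < _EPS):
        j = int(np.argmin(norms))
        raise ValueError(f"zero variance in column {j}")

    max_steps = min(m, np.linalg.matrix_rank(X))
    beta = np.zeros(m)
    path = [beta.copy()]
    active: list[int] = []
    inactive = list(range(m))
    residual = y - y.mean()

    for _ in range(max_steps):
        c = X.T @ residual
        if not inactive:
            break
        c_in = np.abs(c[inactive])
        C = c_in.max()
        if C < _EPS:
            break
        # smallest index among ties
        j_new = inactive[int(np.argmax(c_in > C - _EPS))]
        active.append(j_new)
        inactive.remove(j_new)

        XA = X[:, active]
        s = np.sign(c[active])
        s[s == 0] = 1.0
        G = XA.T @ XA
        try:
            Ginv_s = np.linalg.solve(G, s)
        except np.linalg.LinAlgError:
            active.pop()
            break
        denom = s @ Ginv_s
        if denom <= _EPS:
            active.pop()
            break
        A = 1.0 / np.sqrt(denom)
        w = A * Ginv_s                    # coefficient move (signed) in active set
        u = XA @ w                        # equiangular direction, unit norm
        Cmax = np.abs(c[active]).max()

        a = X.T @ u
        gamma = Cmax / A                  # full step reaches the OLS solution
        if inactive:
            c_in_arr, a_in_arr = c[inactive], a[inactive]
            with np.errstate(divide="ignore", invalid="ignore"):
                cands = np.concatenate(
                    [(Cmax - c_in_arr) / (A - a_in_arr),
                     (Cmax + c_in_arr) / (A + a_in_arr)]
                )
            cands = cands[np.isfinite(cands) & (cands > _EPS)]
            if cands.size:
                gamma = min(gamma, float(cands.min()))

        beta = beta.copy()
        for idx, j in enumerate(active):
            beta[j] += gamma * w[idx]
        residual = residual - gamma * u
        path.append(beta.copy())

    return LarsPath(entry_order=active, coefficient_path=np.array(path))
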