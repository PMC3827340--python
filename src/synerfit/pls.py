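"""Multi-response partial least squares (PLS2) by NIPALS, with VIP scores.

The regressor projects predictors and responses onto shared latent score
spaces: per component, an inner loop alternates weight/score updates until
the X-score stabilizes, then X is deflated by its rank-one reconstruction
(X-only deflation; Y-deflation changes nothing for the regression
coefficients because successive X-scores are orthogonal).  With as many
components as the predictor rank, the fitted values coincide with ordinary
least squares.

Variable importance in projection (VIP, Umetrics form) for predictor i over
A components:

    VIP_i = sqrt( m * sum_a w_ia^2 * SSY_a / sum_a SSY_a )

with unit-norm weight vectors w_a and SSY_a the response sum of squares
explained by component a; squared VIPs therefore average to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import StandardizedMatrix, zscore

__all__ = ["PlsModel", "pls_fit", "pls_predict", "vip"]


@dataclass
class PlsModel:
    ncomp: int
    x_weights: np.ndarray        # m x A, unit-norm columns (W)
    x_loadings: np.ndarray       # m x A (P)
    y_loadings: np.ndarray       # q x A (Q)
    x_scores: np.ndarray         # n x A (T), mutually orthogonal
    coef_std: np.ndarray         # m x q on the standardized scale (B)
    x_std: StandardizedMatrix
    y_std: StandardizedMatrix
    ss_y_explained: np.ndarray   # A, standardized-Y sum of squares per component
    ss_y_explained_per_response: np.ndarray  # A x q
    ss_y_total: float
    term_names: list[str] = field(default_factory=list)
    response_names: list[str] = field(default_factory=list)

    @property
    def explained_y_variance(self) -> np.ndarray:
        """Fraction of (standardized) response variance per component."""
        return self.ss_y_explained / self.ss_y_total

    @property
    def coefficients(self) -> np.ndarray:
        """Original-scale coefficient matrix (m x q)."""
        return (
            self.coef_std
            * self.y_std.column_sds[None, :]
            / self.x_std.column_sds[:, None]
        )

    @property
    def intercept(self) -> np.ndarray:
        """Original-scale intercept (q,)."""
        return self.y_std.column_means - self.x_std.column_means @ self.coefficients

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        return pls_predict(self, Xnew)


def pls_fit(
    X: np.ndarray,
    Y: np.ndarray,
    ncomp: int,
    term_names: Sequence[str] | None = None,
    response_names: Sequence[str] | None = None,
    max_iter: int = 2000,
    tol: float = 1e-12,
) -> PlsModel:
    """Fit a PLS2 model with ``ncomp`` latent components.

    X and Y are standardized internally (columns to mean 0, SD 1); the
    stored parameters de-standardize predictions.  ``ncomp`` must lie in
    ``1..min(n-1, m)``.  The inner NIPALS loop errors out if it fails to
    converge within ``max_iter`` iterations.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = X.shape
    q = Y.shape[1]
    if not 1 <= ncomp <= min(n - 1, m):
        raise ValueError(f"ncomp must be in 1..{min(n - 1, m)}, got {ncomp}")

    x_std = zscore(X, names=term_names)
    y_std = zscore(Y, names=response_names)
    X0, Y0 = x_std.values.copy(), y_std.values

    W = np.zeros((m, ncomp))
    P = np.zeros((m, ncomp))
    Q = np.zeros((q, ncomp))
    T = np.zeros((n, ncomp))
    ssy_a = np.zeros(ncomp)
    ssy_aq = np.zeros((ncomp, q))

    Xa = X0
    for a in range(ncomp):
        # start from the response column with the largest residual variance
        u = Y0[:, int(np.argmax(Y0.var(axis=0)))].copy()
        t = np.zeros(n)
        converged = False
        rel_change = np.inf
        for _ in range(max_iter):
            w = Xa.T @ u
            nw = np.linalg.norm(w)
            if nw < 1e-14:
                # no covariance left between X and Y: fall back to the
                # principal direction of the X residual (q becomes ~0)
                _, _, vt = np.linalg.svd(Xa, full_matrices=False)
                w = vt[0]
                nw = 1.0
            w = w / nw
            t_new = Xa @ w
            tt = t_new @ t_new
            if tt < 1e-14:
                raise np.linalg.LinAlgError(
                    f"degenerate component {a + 1}: X residual exhausted"
                )
            qv = Y0.T @ t_new / tt
            nq = np.linalg.norm(qv)
            if nq < 1e-14 or q == 1:
                converged = True
                t = t_new
                break
            u = Y0 @ qv / (qv @ qv)
            rel_change = np.linalg.norm(t_new - t) / max(np.linalg.norm(t_new), 1e-30)
            if rel_change < tol:
                t = t_new
                converged = True
                break
            t = t_new
        # two near-equal latent directions converge linearly and slowly;
        # accept a near-converged score rather than failing the whole fit
        if not converged and rel_change > 1e-6:
            raise RuntimeError(
                f"NIPALS inner loop did not converge for component {a + 1} "
                f"within {max_iter} iterations (relative change {rel_change:.2e})"
            )
        tt = t @ t
        p = Xa.T @ t / tt
        qv = Y0.T @ t / tt
        Xa = Xa - np.outer(t, p)

        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p, qv, t
        ssy_aq[a] = tt * qv**2
        ssy_a[a] = ssy_aq[a].sum()

    # B = W (P'W)^-1 Q'
    coef_std = W @ np.linalg.solve(P.T @ W, Q.T)

    return PlsModel(
        ncomp=ncomp,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
        coef_std=coef_std,
        x_std=x_std,
        y_std=y_std,
        ss_y_explained=ssy_a,
        ss_y_explained_per_response=ssy_aq,
        ss_y_total=float((Y0**2).sum()),
        term_names=list(x_std.column_names),
        response_names=list(y_std.column_names),
    )


def pls_predict(model: PlsModel, Xnew: np.ndarray) -> np.ndarray:
    """Predict responses (original scale) for new predictor rows."""
    Xs = model.x_std.transform(Xnew)
    return model.y_std.inverse(Xs @ model.coef_std)


def vip(model: PlsModel, response: int | None = None) -> np.ndarray:
    """VIP score per predictor; ``response`` selects a per-response variant
    (explained sum of squares of that response only), the default aggregates
    over all responses.  Raises if the model explains no response variance.
    """
    W = model.x_weights
    m = W.shape[0]
    ssy = (
        model.ss_y_explained
        if response is None
        else model.ss_y_explained_per_response[:, response]
    )
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no response variance; VIP undefined")
    return np.sqrt(m * (W**2 @ ssy) / total)
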