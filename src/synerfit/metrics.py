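"""Fit-quality metrics: R-squared, RMSE, and the Theil inequality index.

Theil's U1 is the default accuracy index:

    U1 = RMS(y - yhat) / (RMS(y) + RMS(yhat)),   RMS(v) = sqrt(mean(v^2))

It is 0 for a perfect predictor, 1 when the prediction is identically zero
against a nonzero series (and in the worst case generally), bounded in
[0, 1] by the triangle inequality on RMS norms, and invariant to a common
rescaling of both series.  U2 = RMS(y - yhat) / RMS(y) is available as an
alternative (unbounded above).

R-squared here is the coefficient of determination of the fitted straight
line in the predicted-vs-observed scatter, i.e. the squared Pearson
correlation between y and yhat; it equals 1 exactly when all points fall on
a line.
"""

from __future__ import annotations

import numpy as np

__all__ = ["r2", "rmse", "theil"]


def _check(y, yhat):
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape[0]} vs {yhat.shape[0]}")
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    return y, yhat


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Squared correlation of observed and predicted values (0 when the
    prediction is constant)."""
    y, yhat = _check(y, yhat)
    sy, syh = y.std(), yhat.std()
    if sy == 0 or syh == 0:
        return 1.0 if np.allclose(y, yhat) else 0.0
    return float(np.corrcoef(y, yhat)[0, 1] ** 2)


def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    y, yhat = _check(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def theil(y: np.ndarray, yhat: np.ndarray, variant: str = "u1") -> float:
    """Theil inequality index; smaller is better, 0 for a perfect fit."""
    y, yhat = _check(y, yhat)
    num = np.sqrt(np.mean((y - yhat) ** 2))
    if variant == "u1":
        denom = np.sqrt(np.mean(y**2)) + np.sqrt(np.mean(yhat**2))
    elif variant == "u2":
        denom = np.sqrt(np.mean(y**2))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if denom == 0:
        raise ValueError("Theil index undefined: observed and predicted both zero")
    return float(num / denom)
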