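"""Comparator models for the four-way evaluation: multi-linear regression,
linear PLS, back-propagation neural network (averaged over repeats), and
LARS-PLS, scored per response by R-squared, RMSE and the Theil index.

The BPNN comparator is a single-hidden-layer sigmoidal network; because its
training is stochastic it is fitted under several seeds and the metrics are
averaged across repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .larspls import fit_lars_pls
from .metrics import r2, rmse, theil
from .pls import pls_fit, pls_predict
from .preprocess import zscore

__all__ = [
    "FitMetrics",
    "MlrModel",
    "BpnnModel",
    "fit_mlr",
    "fit_bpnn",
    "repeated_bpnn",
    "compare_models",
    "fit_metrics",
]


@dataclass
class FitMetrics:
    model_name: str
    response_names: list[str]
    r2: np.ndarray
    rmse: np.ndarray
    theil: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": self.model_name,
                "response": self.response_names,
                "r2": self.r2,
                "rmse": self.rmse,
                "theil": self.theil,
            }
        )


def fit_metrics(
    name: str, Y: np.ndarray, Yhat: np.ndarray, response_names=None
) -> FitMetrics:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Yhat = np.atleast_2d(np.asarray(Yhat, dtype=float))
    q = Y.shape[1]
    if response_names is None:
        response_names = [f"y{k + 1}" for k in range(q)]
    return FitMetrics(
        model_name=name,
        response_names=list(response_names),
        r2=np.array([r2(Y[:, k], Yhat[:, k]) for k in range(q)]),
        rmse=np.array([rmse(Y[:, k], Yhat[:, k]) for k in range(q)]),
        theil=np.array([theil(Y[:, k], Yhat[:, k]) for k in range(q)]),
    )


@dataclass
class MlrModel:
    coef: np.ndarray       # p x q
    intercept: np.ndarray  # q

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.coef + self.intercept


def fit_mlr(X: np.ndarray, Y: np.ndarray) -> MlrModel:
    """Ordinary least squares with intercept, linear terms only.

    Requires n > p and a full-column-rank design."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more runs ({n}) than components ({p})")
    A = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(A) < p + 1:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    sol, *_ = np.linalg.lstsq(A, Y, rcond=None)
    return MlrModel(coef=sol[1:], intercept=sol[0])


@dataclass
class BpnnModel:
    nets: list[MLPRegressor]
    x_std: object
    y_std: object

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = self.x_std.transform(np.atleast_2d(np.asarray(X, dtype=float)))
        Ys = np.asarray(self.nets[0].predict(Xs), dtype=float)
        if Ys.ndim == 1:
            Ys = Ys[:, None]
        return self.y_std.inverse(Ys)


def fit_bpnn(
    X: np.ndarray,
    Y: np.ndarray,
    hidden_units: int = 5,
    seed: int = 1,
    max_iter: int = 2000,
    learning_rate: float = 0.01,
) -> BpnnModel:
    """Single-hidden-layer sigmoidal network on standardized data."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    x_std, y_std = zscore(X), zscore(Y)
    net = MLPRegressor(
        hidden_layer_sizes=(hidden_units,),
        activation="logistic",
        solver="adam",
        learning_rate_init=learning_rate,
        max_iter=max_iter,
        random_state=seed,
        tol=1e-8,
    )
    net.fit(x_std.values, y_std.values if Y.shape[1] > 1 else y_std.values.ravel())
    if not np.isfinite(net.loss_):
        raise RuntimeError("BPNN training diverged (non-finite loss)")
    return BpnnModel(nets=[net], x_std=x_std, y_std=y_std)


def repeated_bpnn(
    X: np.ndarray,
    Y: np.ndarray,
    reps: int = 10,
    seeds: list[int] | None = None,
    response_names=None,
    **kwargs,
) -> FitMetrics:
    """Average training metrics over ``reps`` independently seeded fits."""
    if seeds is None:
        seeds = list(range(1, reps + 1))
    if len(seeds) != reps or len(set(seeds)) != reps:
        raise ValueError("need exactly `reps` distinct seeds")
    Y2 = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y2.shape[0] == 1:
        Y2 = Y2.T
    all_metrics = []
    for s in seeds:
        model = fit_bpnn(X, Y2, seed=s, **kwargs)
        all_metrics.append(
            fit_metrics("bpnn", Y2, model.predict(X), response_names)
        )
    return FitMetrics(
        model_name="bpnn (avg of %d)" % reps,
        response_names=all_metrics[0].response_names,
        r2=np.mean([m.r2 for m in all_metrics], axis=0),
        rmse=np.mean([m.rmse for m in all_metrics], axis=0),
        theil=np.mean([m.theil for m in all_metrics], axis=0),
    )


def compare_models(
    X: np.ndarray,
    Y: np.ndarray,
    models: list[str] = ("mlr", "pls", "bpnn", "larspls"),
    response_names=None,
    bpnn_reps: int = 10,
    ncomp: int | None = None,
) -> pd.DataFrame:
    """Fit every requested comparator on (X, Y) and tabulate per-response
    training metrics (one row per model x response)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if not models:
        raise ValueError("need at least one model spec")
    n, p = X.shape
    frames = []
    for name in models:
        if name == "mlr":
            mdl = fit_mlr(X, Y)
            fm = fit_metrics("mlr", Y, mdl.predict(X), response_names)
        elif name == "pls":
            a = ncomp if ncomp is not None else min(n - 1, p)
            mdl = pls_fit(X, Y, ncomp=a, response_names=response_names)
            fm = fit_metrics("pls", Y, pls_predict(mdl, X), response_names)
        elif name == "bpnn":
            fm = repeated_bpnn(X, Y, reps=bpnn_reps, response_names=response_names)
        elif name == "larspls":
            a = ncomp  # None -> LOO selection inside the pipeline
            mdl = fit_lars_pls(X, Y, ncomp=a, response_names=response_names)
            fm = fit_metrics("larspls", Y, mdl.predict(X), response_names)
        else:
            raise ValueError(f"unknown model spec {name!r}")
        frames.append(fm.to_frame())
    return pd.concat(frames, ignore_index=True)
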