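"""LARS-PLS: quadratic term expansion + PLS regression for small designs.

The pipeline fits multi-endpoint dose-response models from designed
experiments with very few runs (typically 9 runs, 3 components, 5
endpoints):

1. z-score the dose matrix column-wise;
2. expand it with all quadratic terms (squares and pairwise products) in the
   canonical order X1..Xp, X1X1, X1X2, X2X2, X1X3, X2X3, X3X3, ...;
3. order the expanded terms by a least angle regression pass (reported for
   interpretation; optionally the first k entrants are kept);
4. re-standardize the retained terms (products of z-scores are not
   z-scores) and fit a NIPALS PLS2 model;
5. back-project the latent-space coefficients to an explicit quadratic
   polynomial in the original doses (original-scale coefficients plus
   intercept).

The number of latent components defaults to a leave-one-out CV choice,
capped at n-2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .lars import LarsPath, lars_order
from .pls import PlsModel, pls_fit, vip
from .preprocess import StandardizedMatrix, zscore

__all__ = [
    "ExpandedMatrix",
    "LarsPlsModel",
    "expand_quadratic",
    "fit_lars_pls",
    "select_ncomp",
    "select_terms_and_ncomp",
    "design_identifiable_terms",
    "loo_press",
]


@dataclass
class ExpandedMatrix:
    values: np.ndarray
    term_names: list[str]
    # (i, j) column-index pairs for product terms, None for originals
    term_pairs: list[tuple[int, int] | None]


def quadratic_pairs(p: int) -> list[tuple[int, int]]:
    """Index pairs (i, j), i <= j, in canonical order: (0,0), (0,1), (1,1),
    (0,2), (1,2), (2,2), ..."""
    return [(i, j) for j in range(p) for i in range(j + 1)]


def expand_quadratic(
    X: np.ndarray, names: Sequence[str] | None = None
) -> ExpandedMatrix:
    """Append all squares and pairwise products to the columns of ``X``.

    Output has m = p + p(p+1)/2 columns; product columns are elementwise
    products of the input columns (no recentering here).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least one column")
    if names is None:
        names = [f"X{j + 1}" for j in range(p)]
    names = list(names)

    pairs = quadratic_pairs(p)
    cols = [X[:, j] for j in range(p)] + [X[:, i] * X[:, j] for i, j in pairs]
    term_names = names + [f"{names[i]}*{names[j]}" for i, j in pairs]
    term_pairs: list[tuple[int, int] | None] = [None] * p + list(pairs)
    return ExpandedMatrix(np.column_stack(cols), term_names, term_pairs)


@dataclass
class LarsPlsModel:
    """Fitted LARS-PLS pipeline; ``predict`` runs the full chain on raw doses."""

    component_names: list[str]
    x_std: StandardizedMatrix            # dose-scale standardization (p cols)
    expansion: ExpandedMatrix            # expansion of standardized training X
    selected_terms: list[int]            # indices into expansion.term_names
    lars_path: LarsPath | None
    pls: PlsModel
    mode: str
    original_coefficients: np.ndarray = field(default=None)  # m_full x q
    original_intercept: np.ndarray = field(default=None)     # q

    @property
    def term_names(self) -> list[str]:
        return [self.expansion.term_names[k] for k in self.selected_terms]

    @property
    def response_names(self) -> list[str]:
        return self.pls.response_names

    def expand(self, Xnew: np.ndarray) -> np.ndarray:
        """Standardize raw doses and apply the quadratic expansion + term
        selection (model's predictor matrix on the pre-PLS scale)."""
        Z = self.x_std.transform(Xnew)
        E = expand_quadratic(Z, self.x_std.column_names)
        return E.values[:, self.selected_terms]

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        if Xnew.shape[1] != len(self.component_names):
            raise ValueError(
                f"expected {len(self.component_names)} dose columns, "
                f"got {Xnew.shape[1]}"
            )
        from .pls import pls_predict

        return pls_predict(self.pls, self.expand(Xnew))

    def vip(self, response: int | None = None) -> np.ndarray:
        return vip(self.pls, response=response)


def loo_press(
    X: np.ndarray,
    Y: np.ndarray,
    ncomp: int,
    mode: str = "all-terms",
    n_select: int | None = None,
) -> float:
    """Leave-one-out prediction error (summed squared, standardized per
    response by the full-data SD) of the pipeline at a fixed configuration.
    Returns inf if any fold fails."""
    n = X.shape[0]
    y_sd = Y.std(axis=0, ddof=1)
    sse = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = fit_lars_pls(
                X[keep], Y[keep], mode=mode, n_select=n_select,
                ncomp=ncomp, compute_lars=(mode == "lars-select"),
            )
            yhat = model.predict(X[i])
        except (ValueError, np.linalg.LinAlgError, RuntimeError):
            return float("inf")
        sse += float((((yhat[0] - Y[i]) / y_sd) ** 2).sum())
    return sse


def select_ncomp(
    X: np.ndarray,
    Y: np.ndarray,
    method: str = "loo",
    mode: str = "all-terms",
    n_select: int | None = None,
    max_ncomp: int | None = None,
) -> int:
    """Leave-one-out choice of the number of PLS components.

    For each candidate A the pipeline (in the given mode) is refit n times
    with one run held out; the A minimizing the summed out-of-fold squared
    error over responses is returned (smallest A on ties).  Bounded above
    by min(n-2, m).
    """
    if method != "loo":
        raise ValueError(f"unknown method {method!r}")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 runs for LOO selection")
    m = p + p * (p + 1) // 2
    cap = min(n - 2, m)
    if n_select is not None:
        cap = min(cap, n_select)
    if max_ncomp is not None:
        cap = min(cap, max_ncomp)

    press = np.array([
        loo_press(X, Y, a, mode=mode, n_select=n_select)
        for a in range(1, cap + 1)
    ])
    if not np.isfinite(press).any():
        return 1
    return int(np.argmin(press)) + 1


def design_identifiable_terms(X: np.ndarray, rtol: float = 1e-3) -> list[int]:
    """Indices of expanded terms identifiable from the design alone.

    The centered, standardized quadratic expansion of a small design can be
    (near-)rank-deficient — e.g. when two dose columns are linearly aliased
    by the level layout — leaving coefficient directions the data cannot
    determine.  This computes the null directions of the expansion (singular
    values below ``rtol`` times the largest; the default tolerance treats
    relations broken only by printed-table rounding as exact) and greedily
    drops, per null direction, the term carrying the largest null-space
    weight, so the remaining terms admit a unique fit.  Depends only on the
    dose design, never on responses.
    """
    from .preprocess import zscore as _z

    xs = _z(np.atleast_2d(np.asarray(X, dtype=float)))
    es = _z(expand_quadratic(xs.values).values).values
    M = es - es.mean(axis=0)
    _, s, vt = np.linalg.svd(M)
    rank = int(np.sum(s > rtol * s[0]))
    B = vt[rank:].copy()
    keep = list(range(es.shape[1]))
    while B.shape[0]:
        k = keep[int(np.argmax(np.linalg.norm(B[:, keep], axis=0)))]
        keep.remove(k)
        piv = int(np.argmax(np.abs(B[:, k])))
        B = np.delete(B - np.outer(B[:, k] / B[piv, k], B[piv]), piv, axis=0)
    return sorted(keep)


def select_terms_and_ncomp(
    X: np.ndarray, Y: np.ndarray, max_terms: int | None = None
) -> tuple[int, int]:
    """Joint leave-one-out choice of (number of LARS entrants kept, number
    of PLS components): minimizes the LOO prediction error over the grid
    k = 1..min(m, n-1), A = 1..min(k, n-2), smallest (k, A) on ties."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = p + p * (p + 1) // 2
    kmax = min(m, n - 1)
    if max_terms is not None:
        kmax = min(kmax, max_terms)
    best = (1, 1)
    best_press = float("inf")
    for k in range(1, kmax + 1):
        for a in range(1, min(k, n - 2) + 1):
            press = loo_press(X, Y, a, mode="lars-select", n_select=k)
            if press < best_press - 1e-12:
                best_press = press
                best = (k, a)
    return best


def fit_lars_pls(
    X: np.ndarray,
    Y: np.ndarray,
    mode: str = "all-terms",
    n_select: int | None = None,
    ncomp: int | None = None,
    component_names: Sequence[str] | None = None,
    response_names: Sequence[str] | None = None,
    compute_lars: bool = True,
    force_terms: Sequence[int] | None = None,
) -> LarsPlsModel:
    """Fit the full LARS-PLS pipeline on raw doses X and endpoints Y.

    mode="all-terms" keeps every expanded term (LARS is run for the reported
    entry order only); mode="lars-select" keeps the first ``n_select``
    entrants of the LARS pass on the summed standardized response.
    ``force_terms`` (lars-select mode) pins the given expanded-term indices
    into the selection regardless of their entry position, the remaining
    slots going to the earliest other entrants.  ``ncomp=None`` triggers
    leave-one-out selection.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 runs")
    if mode not in ("all-terms", "lars-select"):
        raise ValueError(f"unknown mode {mode!r}")

    x_std = zscore(X, names=component_names)
    expansion = expand_quadratic(x_std.values, x_std.column_names)
    e_std = zscore(expansion.values, names=expansion.term_names)

    path: LarsPath | None = None
    if compute_lars or mode == "lars-select":
        # one LARS pass against the pooled standardized response
        y_pool = zscore(Y).values.sum(axis=1)
        path = lars_order(e_std.values, y_pool)

    if mode == "lars-select":
        if n_select is None:
            raise ValueError("mode='lars-select' requires n_select")
        chosen = list(force_terms) if force_terms else []
        for idx in path.entry_order:
            if len(chosen) >= n_select:
                break
            if idx not in chosen:
                chosen.append(idx)
        selected = sorted(chosen)
        if not selected:
            raise ValueError("LARS selected no terms")
    else:
        selected = list(range(expansion.values.shape[1]))

    E_sel = expansion.values[:, selected]
    sel_names = [expansion.term_names[k] for k in selected]

    if ncomp is None:
        ncomp = select_ncomp(X, Y, mode=mode, n_select=n_select)
    rank = np.linalg.matrix_rank(E_sel - E_sel.mean(axis=0))
    ncomp = int(min(ncomp, rank, n - 1, len(selected)))

    pls = pls_fit(
        E_sel, Y, ncomp,
        term_names=sel_names, response_names=response_names,
    )

    model = LarsPlsModel(
        component_names=list(x_std.column_names),
        x_std=x_std,
        expansion=expansion,
        selected_terms=selected,
        lars_path=path,
        pls=pls,
        mode=mode,
    )
    coef, intercept = _back_project(model)
    model.original_coefficients = coef
    model.original_intercept = intercept
    return model


def _back_project(model: LarsPlsModel) -> tuple[np.ndarray, np.ndarray]:
    """Express the fitted model as an explicit quadratic polynomial in the
    original (unstandardized) doses.

    Every retained term is a product of dose z-scores, itself re-centered
    and scaled before PLS; expanding those affine maps symbolically yields
    exact coefficients on 1, x_i and x_i*x_j.  Rows follow the canonical
    expanded-term order over the *full* expansion (terms never selected get
    zero coefficients).
    """
    p = len(model.component_names)
    q = len(model.pls.response_names)
    mu, sd = model.x_std.column_means, model.x_std.column_sds
    pairs = quadratic_pairs(p)
    n_terms = p + len(pairs)
    monomial_index = {(j,): j for j in range(p)}
    monomial_index.update({(i, j): p + k for k, (i, j) in enumerate(pairs)})

    coef = np.zeros((n_terms, q))
    intercept = np.zeros(q)

    B = model.pls.coef_std                      # selected-terms x q, std scale
    t_mean = model.pls.x_std.column_means
    t_sd = model.pls.x_std.column_sds
    y_mean = model.pls.y_std.column_means
    y_sd = model.pls.y_std.column_sds

    intercept += y_mean
    for row, k in enumerate(model.selected_terms):
        # weight of this term in each response, on the raw-term scale
        wk = y_sd * B[row] / t_sd[row]          # (q,)
        intercept -= wk * t_mean[row]
        pair = model.expansion.term_pairs[k]
        if pair is None:                        # linear term z_i
            i = k
            intercept += wk * (-mu[i] / sd[i])
            coef[monomial_index[(i,)]] += wk / sd[i]
        else:                                   # product z_i * z_j
            i, j = pair
            denom = sd[i] * sd[j]
            intercept += wk * (mu[i] * mu[j] / denom)
            coef[monomial_index[(i,)]] += wk * (-mu[j] / denom)
            coef[monomial_index[(j,)]] += wk * (-mu[i] / denom)
            coef[monomial_index[(min(i, j), max(i, j))]] += wk / denom
    return coef, intercept
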