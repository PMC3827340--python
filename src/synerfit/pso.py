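"""Particle swarm search over the dose space, with a desirability
scalarization turning five predicted endpoints into one fitness value.

Each particle carries a candidate dose vector; velocities are updated
toward the particle's personal best and the swarm's global best with
constriction-type constants (w=0.729, c1=c2=1.49445).  Positions are
clipped to the box bounds and the velocity component reflected on contact.
A fixed seed makes the search reproducible.

Because the assays disagree on which direction is "better" (viability,
membrane potential and the red/green ratio improve upward; the swelling
slope and membrane viscosity improve downward), each predicted endpoint is
mapped to [0, 1] by a linear ramp between a worst and a best anchor
(clipped outside), and the per-endpoint desirabilities are combined by a
weighted arithmetic mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ScalarizationSpec",
    "PsoConfig",
    "OptimizationResult",
    "desirability",
    "pso_minimize",
    "pso_maximize",
    "find_optimal_composition",
]


@dataclass
class ScalarizationSpec:
    """Per-endpoint anchors (worst_value, best_value) and weights.

    The direction of benefit is encoded by the anchor order: for
    lower-is-better endpoints the worst anchor is numerically larger than
    the best one.  Weights are normalized to sum to 1.
    """

    endpoint_names: list[str]
    anchors: Mapping[str, tuple[float, float]]   # name -> (worst, best)
    weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for name in self.endpoint_names:
            if name not in self.anchors:
                raise ValueError(f"missing anchors for endpoint {name!r}")
            worst, best = self.anchors[name]
            if worst == best:
                raise ValueError(f"anchors for {name!r} must be distinct")
        if self.weights is None:
            self.weights = {n: 1.0 for n in self.endpoint_names}
        w = np.array([self.weights.get(n, 0.0) for n in self.endpoint_names])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("weights must be non-negative, not all zero")
        self._w = w / w.sum()

    @property
    def normalized_weights(self) -> np.ndarray:
        return self._w


def desirability(yhat: np.ndarray, spec: ScalarizationSpec) -> np.ndarray:
    """Weighted-mean linear desirability of endpoint values in [0, 1].

    Accepts a single q-vector or an (n, q) batch aligned with
    ``spec.endpoint_names``; returns a scalar or an n-vector.
    """
    Y = np.atleast_2d(np.asarray(yhat, dtype=float))
    q = len(spec.endpoint_names)
    if Y.shape[1] != q:
        raise ValueError(f"expected {q} endpoint values, got {Y.shape[1]}")
    worst = np.array([spec.anchors[n][0] for n in spec.endpoint_names])
    best = np.array([spec.anchors[n][1] for n in spec.endpoint_names])
    d = np.clip((Y - worst) / (best - worst), 0.0, 1.0)
    out = d @ spec.normalized_weights
    return float(out[0]) if np.asarray(yhat).ndim == 1 else out


@dataclass
class PsoConfig:
    swarm_size: int = 30
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    iterations: int = 200
    seed: int = 42

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")


@dataclass
class OptimizationResult:
    best_doses: np.ndarray
    fitness: float
    predicted_endpoints: np.ndarray | None
    trace: np.ndarray                      # per-iteration best (maximization scale)
    n_evaluations: int = 0
    seed: int | None = None
    endpoint_names: list[str] = field(default_factory=list)


def pso_minimize(
    f: Callable[[np.ndarray], np.ndarray],
    bounds: Sequence[tuple[float, float]],
    config: PsoConfig | None = None,
) -> OptimizationResult:
    """Minimize ``f`` over a box; ``f`` maps an (n, d) position array to n
    finite values (non-finite values abort the search)."""
    res = pso_maximize(lambda x: -np.asarray(f(x), dtype=float), bounds, config)
    res.fitness = -res.fitness
    res.trace = -res.trace
    return res


def pso_maximize(
    f: Callable[[np.ndarray], np.ndarray],
    bounds: Sequence[tuple[float, float]],
    config: PsoConfig | None = None,
) -> OptimizationResult:
    config = config or PsoConfig()
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(lo >= hi):
        raise ValueError("each bound must satisfy low < high")
    d = lo.size
    rng = np.random.default_rng(config.seed)

    pos = rng.uniform(lo, hi, size=(config.swarm_size, d))
    span = hi - lo
    vel = rng.uniform(-span, span, size=(config.swarm_size, d)) * 0.1

    def evaluate(p: np.ndarray) -> np.ndarray:
        vals = np.asarray(f(p), dtype=float).ravel()
        if vals.shape[0] != p.shape[0]:
            raise ValueError("objective must return one value per particle")
        if not np.isfinite(vals).all():
            raise ValueError("objective returned a non-finite value")
        return vals

    fit = evaluate(pos)
    n_eval = config.swarm_size
    pbest_pos, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmax(pbest_fit))
    gbest_pos, gbest_fit = pbest_pos[g].copy(), float(pbest_fit[g])
    trace = [gbest_fit]

    for _ in range(config.iterations):
        r1 = rng.random((config.swarm_size, d))
        r2 = rng.random((config.swarm_size, d))
        vel = (
            config.inertia * vel
            + config.cognitive * r1 * (pbest_pos - pos)
            + config.social * r2 * (gbest_pos - pos)
        )
        pos = pos + vel
        # clip to bounds, reflecting the velocity of the offending coordinate
        low_hit = pos < lo
        high_hit = pos > hi
        vel[low_hit | high_hit] *= -0.5
        pos = np.clip(pos, lo, hi)

        fit = evaluate(pos)
        n_eval += config.swarm_size
        improved = fit > pbest_fit
        pbest_pos[improved] = pos[improved]
        pbest_fit[improved] = fit[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest_fit = float(pbest_fit[g])
            gbest_pos = pbest_pos[g].copy()
        trace.append(gbest_fit)

    return OptimizationResult(
        best_doses=gbest_pos,
        fitness=gbest_fit,
        predicted_endpoints=None,
        trace=np.array(trace),
        n_evaluations=n_eval,
        seed=config.seed,
    )


def default_bounds(model, factor: float = 1.5) -> list[tuple[float, float]]:
    """[0, factor x max training dose] per component (mild extrapolation)."""
    X = model.x_std.inverse()
    return [(0.0, factor * float(X[:, j].max())) for j in range(X.shape[1])]


def find_optimal_composition(
    model,
    bounds: Sequence[tuple[float, float]] | None,
    spec: ScalarizationSpec,
    config: PsoConfig | None = None,
) -> OptimizationResult:
    """Maximize the desirability of the model-predicted endpoints over the
    dose box; reports the best dose vector and its predicted endpoints."""
    if bounds is None:
        bounds = default_bounds(model)

    def objective(P: np.ndarray) -> np.ndarray:
        return desirability(model.predict(P), spec)

    res = pso_maximize(objective, bounds, config)
    res.predicted_endpoints = model.predict(res.best_doses[None, :])[0]
    res.endpoint_names = list(spec.endpoint_names)
    return res
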