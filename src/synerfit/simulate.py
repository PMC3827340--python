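"""Synthetic dose-response simulator calibrated to the verification-study
anchors, plus an end-to-end parameter-recovery harness.

The simulator emulates the study conditions: a 9-run uniform-design dosing
experiment with ~10 animals per group measured on five mitochondrial
endpoints (Resazurin viability fluorescence, PT swelling slope, FP membrane
viscosity, Rho membrane potential in mV, JC1 red/green ratio).  Every
endpoint is an affine image of one shared latent "mitochondrial health"
effect g(d):

    y_k(d) = vehicle_mean_k + (sham_mean_k - vehicle_mean_k) * g(d) + noise

so g = 0 reproduces the untreated (vehicle) means exactly and g = 1 reaches
the sham (uninjured) means; endpoints whose benefit direction is downward
(PT, FP) are handled automatically because their sham mean lies below their
vehicle mean.  g is a concave quadratic with pairwise interactions and a
known interior maximizer (the default surface), or a linear-potency form
with an optional three-way synergy term (the "synergy"/"additive" presets
used by the synergistic-design analyses).

Per-animal noise is Gaussian with SD equal to the vehicle-group SD of each
endpoint; a shared latent factor (loading 0.6) correlates the endpoint
errors within an animal, mimicking animal-level heterogeneity in
mitochondrial state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .design import DesignTable, load_uniform_design
from .larspls import design_identifiable_terms, fit_lars_pls
from .pso import PsoConfig, ScalarizationSpec, find_optimal_composition

__all__ = [
    "CALIBRATION",
    "ENDPOINTS",
    "SurfaceSpec",
    "make_surface",
    "preset_surface",
    "simulate_experiment",
    "anchors_from_calibration",
    "recovery_run",
]

ENDPOINTS = ["Resazurin", "PT", "FP", "Rho", "JC1"]

# verification-experiment anchors: (mean, SD) per endpoint for the uninjured
# (sham) and untreated-injured (vehicle) groups, n = 10 animals each
CALIBRATION: dict[str, dict[str, tuple[float, float]]] = {
    "Resazurin": {"sham": (531.33, 152.53), "vehicle": (330.28, 61.42)},
    "PT": {"sham": (0.152, 0.012), "vehicle": (0.678, 0.011)},
    "FP": {"sham": (3.67, 0.30), "vehicle": (5.89, 3.11)},
    "Rho": {"sham": (131.53, 2.23), "vehicle": (125.17, 4.70)},
    "JC1": {"sham": (26.58, 1.49), "vehicle": (21.80, 3.44)},
}

# default true optimum: an interior point of the 9-run design's dose box
# (the doses of its center run)
DEFAULT_OPTIMUM = np.array([4.364, 2.909, 0.727])
COMPONENTS = ["ginsenosides", "berberine", "jasminoidin"]


@dataclass
class SurfaceSpec:
    """Ground-truth surface: shared effect g(d) plus per-endpoint affine map.

    g(d) = linear . d + d' quad d + tau * (d1 d2 d3)^(1/3); endpoints are
    beta0_k + scale_k * g(d).  ``noise_sd`` is in endpoint units;
    ``noise_loading`` is the shared-latent-factor loading in [0, 1)
    (0 = independent errors).
    """

    component_names: list[str]
    endpoint_names: list[str]
    beta0: np.ndarray            # q, endpoint units (vehicle means)
    scale: np.ndarray            # q, endpoint units (effect at g = 1)
    linear: np.ndarray           # p
    quad: np.ndarray             # p x p symmetric
    tau: float = 0.0
    noise_sd: np.ndarray = None  # q
    noise_loading: float = 0.6
    n_per_group: int = 10

    def effect(self, doses: np.ndarray) -> np.ndarray:
        D = np.atleast_2d(np.asarray(doses, dtype=float))
        g = D @ self.linear + np.einsum("ni,ij,nj->n", D, self.quad, D)
        if self.tau:
            g = g + self.tau * np.cbrt(np.prod(D, axis=1))
        return g

    def evaluate(self, doses: np.ndarray) -> np.ndarray:
        """Noise-free endpoint surface values, (n, q)."""
        g = self.effect(doses)
        return self.beta0[None, :] + g[:, None] * self.scale[None, :]

    def analytic_optimum(self) -> np.ndarray | None:
        """Unconstrained stationary point of the quadratic part (the true
        optimum when quad is negative definite and tau = 0)."""
        if self.tau != 0.0:
            return None
        eig = np.linalg.eigvalsh(self.quad)
        if eig.max() >= 0:
            return None
        return -0.5 * np.linalg.solve(self.quad, self.linear)


def make_surface(
    calibration: Mapping[str, Mapping[str, tuple[float, float]]] = CALIBRATION,
    effect_size: float = 0.9,
    optimum: np.ndarray = DEFAULT_OPTIMUM,
    pairwise_coupling: float = 0.15,
    tau: float = 0.0,
    noise_scale: float = 1.0,
    noise_loading: float = 0.6,
    n_per_group: int = 10,
    endpoint_names: list[str] = ENDPOINTS,
    component_names: list[str] = COMPONENTS,
) -> SurfaceSpec:
    """Calibrated default surface: concave quadratic with its maximum at
    ``optimum``, normalized so g(0) = 0 and g(optimum) = 1 (dose 0 sits at
    the vehicle means, the optimum reaches ``effect_size`` of the way to the
    sham means).  ``pairwise_coupling`` > 0 puts synergistic pairwise
    interaction terms into the truth while keeping it concave."""
    for name in endpoint_names:
        if name not in calibration:
            raise ValueError(f"missing calibration anchors for endpoint {name!r}")
    d_star = np.asarray(optimum, dtype=float)
    p = d_star.size
    if np.any(d_star <= 0):
        raise ValueError("the default optimum must be strictly positive")
    # concave quadratic: -C with C_ii = c_i, C_ij = -coupling*sqrt(c_i c_j);
    # coupling < 1/(p-1) keeps C positive definite
    c = 1.0 / (p * d_star**2)
    C = np.diag(c)
    for i in range(p):
        for j in range(i + 1, p):
            C[i, j] = C[j, i] = -pairwise_coupling * np.sqrt(c[i] * c[j])
    quad = -C
    linear = -2.0 * quad @ d_star
    # normalize so g(d*) = -d*' quad d* = 1 exactly, then g(0) = 0
    g_star = float(-d_star @ quad @ d_star)
    quad, linear = quad / g_star, linear / g_star

    beta0 = np.array([calibration[n]["vehicle"][0] for n in endpoint_names])
    sham = np.array([calibration[n]["sham"][0] for n in endpoint_names])
    scale = (sham - beta0) * effect_size
    noise_sd = noise_scale * np.array(
        [calibration[n]["vehicle"][1] for n in endpoint_names]
    )
    return SurfaceSpec(
        component_names=list(component_names),
        endpoint_names=list(endpoint_names),
        beta0=beta0,
        scale=scale,
        linear=linear,
        quad=quad,
        tau=tau,
        noise_sd=noise_sd,
        noise_loading=noise_loading,
        n_per_group=n_per_group,
    )


# per-mg/kg linear potencies of the three components in the presets
PRESET_POTENCY = np.array([0.022, 0.018, 0.020])
PRESET_TAU = 0.08


def preset_surface(preset: str, n_per_group: int = 10, **kwargs) -> SurfaceSpec:
    """"synergy": linear potencies plus a positive three-way term (the
    combination outperforms every mono/pair split); "additive": the same
    linear potencies with no interaction (it does not)."""
    if preset not in ("synergy", "additive"):
        raise ValueError(f"unknown preset {preset!r}")
    spec = make_surface(n_per_group=n_per_group, **kwargs)
    spec.quad = np.zeros_like(spec.quad)
    spec.linear = PRESET_POTENCY.copy()
    spec.tau = PRESET_TAU if preset == "synergy" else 0.0
    return spec


def simulate_experiment(
    design: DesignTable,
    surface: SurfaceSpec,
    seed: int,
    n_per_group: int | None = None,
) -> pd.DataFrame:
    """Animal-level responses: one row per animal with its group label,
    doses, and noisy endpoint values.  Fixed seed gives bit-identical
    output."""
    doses = design.doses
    if doses.shape[1] != len(surface.component_names):
        raise ValueError("design and surface have different component counts")
    n = n_per_group if n_per_group is not None else surface.n_per_group
    rng = np.random.default_rng(seed)
    truth = surface.evaluate(doses)                    # runs x q
    q = truth.shape[1]

    lam = surface.noise_loading
    rows = []
    t = design.table
    has_label = "label" in t.columns
    for r in range(doses.shape[0]):
        if has_label:
            label = f"{t['label'].iloc[r]}@{t['total'].iloc[r]:g}"
        else:
            label = f"run{int(t['run'].iloc[r])}"
        shared = rng.standard_normal(n)
        indep = rng.standard_normal((n, q))
        noise = surface.noise_sd * (
            lam * shared[:, None] + np.sqrt(1 - lam**2) * indep
        )
        for a in range(n):
            rows.append([label, *doses[r], *(truth[r] + noise[a])])
    return pd.DataFrame(
        rows, columns=["group", *surface.component_names, *surface.endpoint_names]
    )


def anchors_from_calibration(
    calibration=CALIBRATION, endpoint_names=ENDPOINTS
) -> ScalarizationSpec:
    """Desirability anchors: vehicle mean = worst, sham mean = best."""
    return ScalarizationSpec(
        endpoint_names=list(endpoint_names),
        anchors={
            n: (calibration[n]["vehicle"][0], calibration[n]["sham"][0])
            for n in endpoint_names
        },
    )


def recovery_run(
    seed: int,
    surface: SurfaceSpec | None = None,
    design: DesignTable | None = None,
    n_per_group: int | None = None,
    noise_scale: float | None = None,
    pso_config: PsoConfig | None = None,
    ncomp: int | None = None,
) -> dict:
    """Full workflow on simulated data: simulate the 9-run uniform design,
    fit LARS-PLS on the per-run group means, PSO-optimize the desirability,
    and measure the distance to the true surface optimum.

    Returns per-component absolute errors as fractions of each component's
    search range, plus original-scale coefficient errors (RMSE over the nine
    quadratic monomials, normalized by each endpoint's effect scale).
    """
    if surface is None:
        surface = make_surface()
    if noise_scale is not None:
        surface = make_surface(noise_scale=noise_scale,
                               n_per_group=surface.n_per_group)
    if design is None:
        design = load_uniform_design(validate=False)

    animals = simulate_experiment(design, surface, seed=seed,
                                  n_per_group=n_per_group)
    means = animals.groupby("group", sort=False)[
        surface.component_names + surface.endpoint_names
    ].mean()
    X = means[surface.component_names].to_numpy()
    Y = means[surface.endpoint_names].to_numpy()
    n_runs, p = X.shape

    # identifiability-pruned fit: the quadratic expansion of the 9-run
    # design is (near-)rank-deficient, and the surface recovered along its
    # null directions is arbitrary; terms carrying those directions are
    # dropped based on the design alone.  ncomp is held one below the
    # retained-term count (mild shrinkage; PRESS-optimal shrinkage
    # minimizes prediction error, which is not the same objective as
    # locating the surface optimum).
    keep = design_identifiable_terms(X)
    model = fit_lars_pls(
        X, Y,
        mode="lars-select",
        n_select=len(keep),
        force_terms=keep,
        component_names=surface.component_names,
        response_names=surface.endpoint_names,
        ncomp=max(1, len(keep) - 1) if ncomp is None else ncomp,
    )

    # search within the design region: a saturated quadratic fitted from 9
    # runs carries no information beyond the dose box, and the generator's
    # optimum is interior to it
    bounds = [(0.0, float(X[:, j].max())) for j in range(X.shape[1])]
    spec = anchors_from_calibration(endpoint_names=surface.endpoint_names)
    # precision weighting: endpoints whose anchor span is large relative to
    # their within-group noise localize the optimum far better; the weights
    # are estimated from the simulated animal-level data, not the truth
    within_sd = (
        animals.groupby("group")[surface.endpoint_names].std(ddof=1).mean()
    ).to_numpy()
    if np.all(within_sd > 1e-12):
        span = np.array(
            [abs(spec.anchors[n][1] - spec.anchors[n][0])
             for n in surface.endpoint_names]
        )
        spec = ScalarizationSpec(
            endpoint_names=surface.endpoint_names,
            anchors=spec.anchors,
            weights=dict(zip(surface.endpoint_names, (span / within_sd) ** 2)),
        )
    result = find_optimal_composition(
        model, bounds, spec, pso_config or PsoConfig(seed=seed)
    )

    d_true = surface.analytic_optimum()
    report = {
        "seed": seed,
        "estimated_optimum": result.best_doses.tolist(),
        "fitness": result.fitness,
        "ncomp": model.pls.ncomp,
        "bounds": bounds,
    }
    if d_true is not None:
        ranges = np.array([hi - lo for lo, hi in bounds])
        err = np.abs(result.best_doses - d_true)
        report["true_optimum"] = d_true.tolist()
        report["abs_error"] = err.tolist()
        report["relative_error"] = (err / ranges).tolist()
        report["max_relative_error"] = float((err / ranges).max())

    # original-scale coefficient recovery, normalized per endpoint
    true_coef = _true_polynomial(surface)
    est = model.original_coefficients
    denom = np.abs(surface.scale)
    report["coefficient_rmse"] = (
        np.sqrt(((est - true_coef) ** 2).mean(axis=0)) / denom
    ).tolist()
    return report


def _true_polynomial(surface: SurfaceSpec) -> np.ndarray:
    """True original-scale coefficients on the canonical monomials
    (x1..xp, x1^2, x1x2, x2^2, x1x3, x2x3, x3^2) per endpoint."""
    p = surface.linear.size
    from .larspls import quadratic_pairs

    pairs = quadratic_pairs(p)
    g_coef = np.concatenate([
        surface.linear,
        [surface.quad[i, j] if i == j else 2 * surface.quad[i, j]
         for i, j in pairs],
    ])
    return g_coef[:, None] * surface.scale[None, :]
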