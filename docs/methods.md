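# Methods

## The problem

A three-component formulation (ginsenosides G, berberine B, jasminoidin J)
is dosed in rats after experimental cerebral ischemia, and five
mitochondrial endpoints are measured per animal: Resazurin viability
fluorescence (higher is better), PT swelling slope (lower), FP membrane
viscosity η (lower), Rho membrane potential in mV (higher), and the JC1
red/green ratio (higher). The experimental budget is a 9-run uniform
design, about 10 animals per run. The analysis goal is threefold: a
predictive dose-response model, the dose composition maximizing overall
benefit, and a verdict on whether the three components are synergistic.

## Uniform designs and the packaged tables

A U₉(9³) table assigns each component one of nine dose levels per run so
that every level of every component occurs exactly once. The package ships
the study's level matrix and per-component level→dose grids as data rather
than deriving them from a lattice generator: this guarantees bit-exact
reconstruction of the printed doses. Totals are always recomputed from the
component doses; one printed total (run 6) disagrees with its component sum
by 0.182 mg/kg and is flagged, not trusted. Rounding follows the printed
convention: half away from zero, 3 decimals for grid doses, 2 for ratio
doses.

A caveat worth knowing: in the shipped level matrix the G and B level
columns sum to 10 in every run, so those two dose columns are almost
exactly collinear. The quadratic expansion of this design therefore has
null directions (singular values ≲ 1e-4 of the largest, the residual being
printed-table rounding), with consequences for model fitting discussed
below.

## LARS-PLS

The regression pipeline is: z-score the dose columns (sample SD, n−1) →
append all squares and pairwise products in the canonical order
X₁..X₃, X₁², X₁X₂, X₂², X₁X₃, X₂X₃, X₃² → re-standardize the expanded
terms (products of z-scores are not z-scores; PLS weights and VIP need
unit-variance predictors) → NIPALS PLS2 → back-project to an explicit
quadratic polynomial in the original doses (exact symbolic expansion of
the two standardization layers, verified against training predictions to
1e-13).

NIPALS details: deflation of X only (Y-deflation does not change the
coefficients because successive X-scores are orthogonal); inner-loop
tolerance 1e-12 with a budget of 2000 iterations — when two latent
directions are nearly tied the loop converges linearly and slowly, so a
score that has stabilized to 1e-6 relative change is accepted rather than
failing the fit. With ncomp equal to the predictor rank the fitted values
equal the least-squares projection; this oracle equivalence is tested on
100 random 9-run instances.

Term selection. Two modes exist. `all-terms` keeps all nine expanded
terms and runs LARS purely for the reported entry order — this reproduces
the nine-variable VIP analysis. `lars-select` keeps the first k LARS
entrants (ties broken by the lowest column index; entry order verified
against an independent path implementation); specific terms can be pinned
into the selection. The number of components defaults to leave-one-out CV
over the full pipeline, capped at n−2, smallest on ties. Both the LOO
choice of ncomp and of k minimize prediction error; note that prediction
error is not the same objective as locating a surface optimum (see the
recovery harness below).

VIP uses the Umetrics form VIPᵢ = √(m Σₐ wᵢₐ² SSYₐ / Σₐ SSYₐ) with
unit-norm weight vectors; Σ VIP² = m holds identically and is
property-tested. By default SSYₐ aggregates all five endpoints; a
per-response variant is available.

## Comparator models and metrics

The four-model comparison fits multi-linear regression (OLS), linear PLS,
a BPNN and LARS-PLS to the same 9-run data. The BPNN is a single hidden
layer of 5 logistic units trained by adam (learning rate 0.01, 2000
epochs) on standardized data; because training is stochastic, metrics are
averaged over ten fixed seeds (1..10). The architecture and repeat count
are config knobs; the defaults are the smallest standard choice.

Metrics per endpoint: R² (squared correlation of observed and predicted —
the R² of the fitted line in the predicted-vs-observed scatter), RMSE in
endpoint units, and a Theil inequality index. The Theil variant is U₁ =
RMS(y−ŷ)/(RMS(y)+RMS(ŷ)): it is 0 for a perfect predictor, 1 when the
prediction is identically zero, bounded in [0, 1], and invariant to
rescaling both series; U₂ = RMS(y−ŷ)/RMS(y) is switchable.

## Scalarization and PSO

The five predicted endpoints are mapped to a single fitness by linear
desirability: endpoint k with anchors (worst, best) scores
clip((ŷₖ−worst)/(best−worst), 0, 1), and the scores combine by a weighted
arithmetic mean (equal weights by default; anchors default to the vehicle
and sham group means, which encode each assay's direction of benefit with
no extra parameters).

PSO uses the constriction-type constants w = 0.729, c₁ = c₂ = 1.49445,
swarm 30, 200 iterations, fixed seed (default 42). Positions are clipped
to the box and the offending velocity component is reflected (halved and
negated). The global-best trace is monotone by construction; optima are
tested against analytic solutions and a 21³ brute-force grid.

Search bounds for general use default to [0, 1.5 × max training dose] per
component with an explicit extrapolation warning: a 9-run quadratic has no
evidence outside its design region.

## Simulator

Each endpoint is an affine image of one shared latent "mitochondrial
health" effect: yₖ(d) = vehicleₖ + (shamₖ − vehicleₖ)·effect_size·g(d) +
noise. Dose 0 reproduces the vehicle means exactly; g is normalized so its
maximum is 1. The default surface is a concave quadratic with pairwise
interaction terms (coupling 0.15 of the geometric mean of the diagonal
curvatures, keeping the Hessian negative definite) whose maximizer is the
center run's dose vector (4.364, 2.909, 0.727) mg/kg — an interior point
of the design box. effect_size defaults to 0.9: the design-region optimum
approaches but does not reach the sham means, so the desirability surface
has a unique maximum rather than a clipped plateau.

Noise is Gaussian per animal with SD equal to each endpoint's vehicle-group
SD (the published calibration anchors), correlated across endpoints within
an animal through a shared latent factor with loading 0.6 (sign-aligned
with each endpoint's benefit direction); independent noise is switchable.
The presets used by the synergy analyses replace the quadratic with linear
per-mg potencies (0.022, 0.018, 0.020 per mg/kg — roughly equal effects at
25 mg/kg mono-dosing) plus, in the `synergy` preset only, a three-way term
τ·(d₁d₂d₃)^(1/3) with τ = 0.08, which rewards only the full combination;
the `additive` preset sets τ = 0. The cube-root form keeps the synergy
bonus comparable across the 5 and 25 mg/kg total-dose tiers.

What the simulator does not emulate: pharmacokinetics, assay-specific
error distributions (all noise is Gaussian), between-batch effects, and
any endpoint correlation structure beyond the single shared factor.
Passing benchmarks therefore demonstrate that the pipeline recovers the
truth of a well-specified smooth surface under realistic noise magnitudes,
not that it is robust to model misspecification.

## Recovery harness

`recovery_run` executes the full loop: simulate the 9-run design → average
animals to 9 group means → fit LARS-PLS → PSO-maximize desirability →
compare against the generator's analytic optimum. Three choices matter,
all consequences of the design's near-collinearity:

- **Identifiability pruning.** The expanded design has null directions;
  coefficients along them are arbitrary, and the min-norm (full-PLS)
  interpolant's argmax can sit far from the truth even on noiseless data.
  `design_identifiable_terms` finds the null directions of the expanded
  design (rank tolerance 1e-3 relative, treating relations broken only by
  printed rounding as exact) and greedily drops, per direction, the term
  carrying the largest null-space weight. The rule depends only on the
  dose design, never on responses.
- **Fixed shrinkage.** ncomp is held at (number of kept terms − 1) rather
  than chosen by LOO: PRESS-optimal shrinkage flattens the surface and
  biases its argmax, which LOO cannot see.
- **Precision weighting.** Desirability weights are set to (anchor span /
  within-group SD)², with the SD estimated from the simulated animal
  table. Endpoints that localize the optimum sharply (the PT slope has a
  tiny SD relative to its dynamic range) then dominate the fitness, as
  they should; with noise-free data the weights fall back to equal.

Benchmarks at these settings: noiseless recovery within 2 % of each
component's range; with calibrated noise and n = 10, the 20-seed median
per-component error stays below 15 % of range (measured ≈ 2–6 %), and the
median error grows monotonically as the noise SD scales 0.5× → 1× → 2×.

## Synergy scoring

Lower-is-better endpoints (PT, FP) are negated, columns are z-scored over
the full animal pool (per-experiment standardization is the documented
alternative), and PC1 of the pooled matrix is the per-animal composite
score. The PC sign is arbitrary, so scores are oriented to place the sham
group above the vehicle group (fallback: positive loading on the
viability endpoint). Group differences use the classical one-way ANOVA F;
the synergy verdict at each total dose requires the full combination's
mean score to exceed every mono and pair group's mean AND every Welch
pairwise comparison to be significant at α = 0.05 after Holm correction
(unadjusted comparisons are switchable, matching star-style reporting).

## Known limitations

- The 9-run design cannot identify a full three-factor quadratic; the
  pruning above makes the fit unique but assumes the dropped directions
  carry no real signal. A design without aliased columns would remove the
  issue at the source.
- Desirability anchors derived from sham/vehicle means are themselves
  estimates; their sampling error is ignored.
- The BPNN comparator is a reference point, not a tuned competitor.
- The synergy verdict treats animals as exchangeable across groups
  (no litter or batch structure).
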