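# synerfit

Dose-ratio optimization for multi-component drugs from small designed
experiments.

Multi-herb formulations (and combination drugs generally) pose a concrete
statistical problem: with three active components and an animal budget of
nine treatment groups, find the dose composition that best restores a panel
of pharmacological endpoints, and decide whether the components act
synergistically. `synerfit` implements the complete desk-side workflow for
this problem, aimed at pharmacologists analyzing uniform-design dosing
studies:

1. **Design** — build and validate U<sub>9</sub>(9³) uniform-design dose
   tables (each component visits each of its nine dose levels exactly once)
   and full/mono/pair "synergistic" designs at fixed total doses.
2. **LARS-PLS regression** — fit a multi-endpoint dose-response model on
   n = 9 runs: z-score the doses, expand with all quadratic terms
   (X₁, X₂, X₃, X₁², X₁X₂, X₂², X₁X₃, X₂X₃, X₃²), order/prune terms by
   least angle regression, fit a NIPALS PLS2 model on the re-standardized
   terms, and back-project to an explicit polynomial in the original doses.
   Comparators: multi-linear regression, linear PLS, and a back-propagation
   network averaged over ten seeds, scored per endpoint by R², RMSE and
   Theil's U₁ = RMS(y−ŷ) / (RMS(y) + RMS(ŷ)).
3. **Composition search** — particle swarm optimization over the dose box,
   maximizing a desirability scalarization that maps each predicted
   endpoint onto [0, 1] between a worst (vehicle) and best (sham) anchor,
   respecting each assay's direction of benefit.
4. **Interpretation** — VIP scores
   (VIPᵢ = √(m · Σₐ wᵢₐ² SSYₐ / Σₐ SSYₐ), so mean squared VIP = 1) rank the
   expanded terms; a PCA composite of the five mitochondrial endpoints with
   one-way ANOVA and Welch pairwise tests delivers a per-dose synergy
   verdict (full combination vs every mono and pair group).
5. **Simulation** — a response-surface generator calibrated to published
   sham/vehicle endpoint means and SDs (Resazurin viability fluorescence,
   PT swelling slope, FP membrane viscosity, Rho membrane potential, JC1
   red/green ratio) drives end-to-end parameter-recovery and
   synergy-detection benchmarks.

## Worked example

Recover a known optimum from a simulated 9-run study (10 animals/group,
noise calibrated to the published vehicle-group SDs):

```python
from synerfit.simulate import recovery_run

rep = recovery_run(seed=7)
print(rep["true_optimum"])       # [4.364, 2.909, 0.727]  mg/kg (G, B, J)
print(rep["estimated_optimum"])  # [4.464, 2.986, 0.732]
print(rep["relative_error"])     # [0.0153, 0.0177, 0.0048] of each range
```

The workflow simulates the uniform-design experiment, fits the LARS-PLS
model on the nine group means, and PSO-maximizes the predicted
desirability: the estimated optimal composition lands within ~2 % of each
component's dose range of the generator's true optimum.

VIP scores from the same fit rank term influence (values ≫ 1 matter most;
here the curvature and G×B interaction terms dominate, as built into the
simulated surface):

```
ginsenosides                 0.581
berberine                    0.756
jasminoidin                  0.786
ginsenosides*ginsenosides    1.171
ginsenosides*berberine       1.313
berberine*berberine          1.245
...
```

The same pipeline is available from the shell:

```
synerfit design make --out design.csv
synerfit simulate --preset default --seed 7 --out animals.csv
synerfit fit --design design.csv --responses means.csv --out model.json
synerfit optimize --design design.csv --responses means.csv --seed 42 --out optimum.json
synerfit synergy --responses animals14.csv --out synergy.json
synerfit recover --seeds 1..20 --out recovery.json
```

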