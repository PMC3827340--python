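"""Particle swarm search and the desirability scalarization."""

import numpy as np
import pytest

from synerfit.pso import (PsoConfig, ScalarizationSpec, desirability,
                          find_optimal_composition, pso_maximize, pso_minimize)


def sphere(x):
    return (np.atleast_2d(x) ** 2).sum(axis=1)


class TestDesirability:
    def spec(self, w=None):
        return ScalarizationSpec(
            endpoint_names=["up", "down"],
            anchors={"up": (0.0, 10.0), "down": (5.0, 1.0)},
            weights=w,
        )

    def test_best_anchors_give_one(self):
        assert desirability(np.array([10.0, 1.0]), self.spec()) == 1.0

    def test_worst_anchors_give_zero(self):
        assert desirability(np.array([0.0, 5.0]), self.spec()) == 0.0

    def test_midpoint_with_unit_weight(self):
        spec = self.spec(w={"up": 1.0, "down": 0.0})
        assert desirability(np.array([5.0, 123.0]), spec) == pytest.approx(0.5)

    def test_clipping_outside_anchors(self):
        assert desirability(np.array([20.0, -3.0]), self.spec()) == 1.0

    def test_identical_anchors_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ScalarizationSpec(["a"], {"a": (1.0, 1.0)})

    def test_missing_endpoint_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            ScalarizationSpec(["a", "b"], {"a": (0.0, 1.0)})


class TestPso:
    def test_sphere_minimum(self):
        res = pso_minimize(sphere, [(-5, 5)] * 3, PsoConfig(seed=1))
        np.testing.assert_allclose(res.best_doses, 0, atol=1e-3)
        assert res.fitness == pytest.approx(0.0, abs=1e-5)

    def test_shifted_quadratic(self):
        f = lambda x: (np.atleast_2d(x)[:, 0] - 1) ** 2 + (np.atleast_2d(x)[:, 1] + 2) ** 2
        res = pso_minimize(f, [(-5, 5), (-5, 5)], PsoConfig(seed=2))
        np.testing.assert_allclose(res.best_doses, [1.0, -2.0], atol=1e-3)

    def test_constrained_optimum_on_boundary(self):
        f = lambda x: (np.atleast_2d(x)[:, 0] - 10) ** 2
        res = pso_minimize(f, [(0, 5)], PsoConfig(seed=3))
        assert res.best_doses[0] == pytest.approx(5.0, abs=1e-6)

    def test_trace_monotone_and_within_bounds(self):
        res = pso_maximize(lambda x: -sphere(x), [(-4, 4)] * 2, PsoConfig(seed=4))
        assert (np.diff(res.trace) >= 0).all()
        assert (np.abs(res.best_doses) <= 4).all()

    def test_reproducible_for_fixed_seed(self):
        a = pso_minimize(sphere, [(-5, 5)] * 2, PsoConfig(seed=7))
        b = pso_minimize(sphere, [(-5, 5)] * 2, PsoConfig(seed=7))
        np.testing.assert_array_equal(a.best_doses, b.best_doses)
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_nonfinite_objective_rejected(self):
        f = lambda x: np.full(np.atleast_2d(x).shape[0], np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            pso_minimize(f, [(0, 1)], PsoConfig(seed=1))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError, match="low < high"):
            pso_minimize(sphere, [(2, 2)], PsoConfig(seed=1))

    def test_small_swarm_rejected(self):
        with pytest.raises(ValueError, match="swarm_size"):
            PsoConfig(swarm_size=1)


class TestFindOptimalComposition:
    def _fit_quadratic_model(self, uniform_design):
        from synerfit.larspls import design_identifiable_terms, fit_lars_pls

        X = uniform_design.doses
        # concave paraboloid with interior maximum at (4, 2.5, 0.6); the fit
        # keeps only design-identifiable terms (the 9-run expansion has a
        # null space) so the fitted surface matches the truth in the box
        d0 = np.array([4.0, 2.5, 0.6])
        g = 1 - (((X - d0) / [4.0, 2.5, 0.6]) ** 2).sum(1) / 3
        Y = np.column_stack([100 + 50 * g, 10 - 5 * g])
        keep = design_identifiable_terms(X)
        # the truth has no cross terms, so it is exactly representable in
        # the kept basis and a full-rank fit reproduces it
        model = fit_lars_pls(
            X, Y, mode="lars-select", n_select=len(keep),
            force_terms=keep, ncomp=len(keep),
        )
        return model, d0

    def test_recovers_interior_optimum(self, uniform_design):
        model, d0 = self._fit_quadratic_model(uniform_design)
        spec = ScalarizationSpec(
            ["a", "b"], {"a": (100.0, 155.0), "b": (10.0, 4.4)}
        )
        bounds = [(0, 6.545), (0, 4.364), (0, 1.091)]
        res = find_optimal_composition(model, bounds, spec, PsoConfig(seed=5))
        ranges = np.array([hi - lo for lo, hi in bounds])
        assert (np.abs(res.best_doses - d0) / ranges < 0.05).all()
        assert res.predicted_endpoints.shape == (2,)

    def test_matches_brute_force_grid(self, uniform_design):
        model, _ = self._fit_quadratic_model(uniform_design)
        spec = ScalarizationSpec(
            ["a", "b"], {"a": (100.0, 150.0), "b": (10.0, 5.0)}
        )
        bounds = [(0, 6.545), (0, 4.364), (0, 1.091)]
        res = find_optimal_composition(model, bounds, spec, PsoConfig(seed=6))
        axes = [np.linspace(lo, hi, 21) for lo, hi in bounds]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = desirability(model.predict(grid), spec)
        best = grid[np.argmax(vals)]
        cell = np.array([(hi - lo) / 20 for lo, hi in bounds])
        assert (np.abs(res.best_doses - best) <= cell + 1e-9).all()

    def test_monotone_surface_pins_to_upper_bound(self, uniform_design):
        from synerfit.larspls import design_identifiable_terms, fit_lars_pls

        X = uniform_design.doses
        Y = (2.0 * X[:, 0] + 0.01 * X[:, 1])[:, None]
        keep = design_identifiable_terms(X)
        model = fit_lars_pls(X, Y, mode="lars-select", n_select=len(keep),
                             force_terms=keep, ncomp=len(keep))
        spec = ScalarizationSpec(["a"], {"a": (0.0, 20.0)})
        bounds = [(0, 6.0), (0, 4.0), (0, 1.0)]
        res = find_optimal_composition(model, bounds, spec, PsoConfig(seed=8))
        assert res.best_doses[0] == pytest.approx(6.0, abs=1e-4)

    def test_two_seeds_agree_on_smooth_surface(self, uniform_design):
        model, _ = self._fit_quadratic_model(uniform_design)
        spec = ScalarizationSpec(
            ["a", "b"], {"a": (100.0, 150.0), "b": (10.0, 5.0)}
        )
        bounds = [(0, 6.545), (0, 4.364), (0, 1.091)]
        r1 = find_optimal_composition(model, bounds, spec, PsoConfig(seed=11))
        r2 = find_optimal_composition(model, bounds, spec, PsoConfig(seed=12))
        assert abs(r1.fitness - r2.fitness) <= 1e-6
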