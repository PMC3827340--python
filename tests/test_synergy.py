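"""Composite PCA score, one-way ANOVA, and the synergy verdict logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synerfit.simulate import ENDPOINTS, preset_surface, simulate_experiment
from synerfit.synergy import composite_score, one_way_anova, synergy_assessment


def _animals(preset, seed, synergy_design):
    surf = preset_surface(preset)
    a = simulate_experiment(synergy_design, surf, seed=seed)
    return a[["group"] + ENDPOINTS]


class TestCompositeScore:
    def test_perfectly_correlated_columns(self, rng):
        base = rng.normal(size=30)
        M = np.column_stack([base * c for c in (1.0, 2.0, 0.5, 3.0, 1.5)])
        df = pd.DataFrame(M, columns=["a", "b", "c", "d", "e"])
        df["group"] = np.repeat(["g1", "g2", "g3"], 10)
        score = composite_score(df, align_directions=False)
        assert score.explained_fraction == pytest.approx(1.0)
        np.testing.assert_allclose(
            np.abs(score.loadings), np.full(5, 1 / np.sqrt(5)), atol=1e-10
        )

    def test_orientation_invariant_to_global_sign_flip(self, synergy_design):
        df = _animals("synergy", 5, synergy_design)
        s1 = composite_score(df, align_directions=False)
        flipped = df.copy()
        for c in ENDPOINTS:
            flipped[c] = -flipped[c]
        # flipping all endpoint values flips the raw PC but the oriented
        # scores preserve the group ordering
        s2 = composite_score(
            flipped, align_directions=False,
            sham_label="none", vehicle_label="none",
        )
        order1 = s1.group_stats.sort_values("mean")["group"].tolist()
        order2 = s2.group_stats.sort_values("mean")["group"].tolist()
        assert order1 == order2 or order1 == order2[::-1]

    def test_sham_oriented_above_vehicle(self, rng):
        healthy = rng.normal(1.0, 0.3, size=(10, 5))
        sick = rng.normal(-1.0, 0.3, size=(10, 5))
        df = pd.DataFrame(np.vstack([healthy, sick]),
                          columns=["a", "b", "c", "d", "e"])
        df["group"] = ["sham"] * 10 + ["vehicle"] * 10
        score = composite_score(df, align_directions=False)
        assert score.group_mean("sham") > score.group_mean("vehicle")

    def test_combo_tops_all_groups_with_synergy(self, synergy_design):
        """Built-in three-way synergy drives the full combination's mean
        composite score above every mono/pair group (20-seed majority)."""
        wins = 0
        for seed in range(1, 21):
            score = composite_score(_animals("synergy", seed, synergy_design))
            means = score.group_stats.set_index("group")["mean"]
            at25 = {g: v for g, v in means.items() if g.endswith("@25")}
            if at25["GBJ@25"] == max(at25.values()):
                wins += 1
        assert wins > 10

    def test_permutation_invariance(self, synergy_design):
        df = _animals("additive", 3, synergy_design)
        perm = np.random.default_rng(0).permutation(len(df))
        s1 = composite_score(df)
        s2 = composite_score(df.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(s1.loadings, s2.loadings, atol=1e-10)
        assert s1.anova_f == pytest.approx(s2.anova_f)

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 1.0], "b": [1, 2, 3, 4.0]})
        df["group"] = ["x", "x", "y", "y"]
        with pytest.raises(ValueError, match="zero variance"):
            composite_score(df)

    def test_pc1_is_best_rank_one_approximation(self, rng):
        """PC1 minimizes reconstruction error among unit directions,
        verified against a dense rotation search on a 3-column toy."""
        from synerfit.preprocess import zscore

        M = rng.normal(size=(12, 3)) @ np.diag([3.0, 1.0, 0.5])
        df = pd.DataFrame(M, columns=["a", "b", "c"])
        df["group"] = ["x"] * 6 + ["y"] * 6
        score = composite_score(df, align_directions=False,
                                sham_label="none", vehicle_label="none")
        Z = zscore(M).values
        best_err = np.inf
        for theta in np.linspace(0, np.pi, 60):
            for phi in np.linspace(0, 2 * np.pi, 120):
                v = np.array([
                    np.sin(theta) * np.cos(phi),
                    np.sin(theta) * np.sin(phi),
                    np.cos(theta),
                ])
                err = ((Z - np.outer(Z @ v, v)) ** 2).sum()
                best_err = min(best_err, err)
        pc1_err = ((Z - np.outer(Z @ score.loadings, score.loadings)) ** 2).sum()
        assert pc1_err <= best_err + 1e-6


class TestAnova:
    def test_equal_means_give_zero(self):
        F, p = one_way_anova(np.array([1, 2, 3, 1, 2, 3.0]),
                             np.array(["a"] * 3 + ["b"] * 3))
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # groups (1,2) and (3,4): SSB = 4, SSW = 1 -> F = 8 with df (1, 2)
        F, p = one_way_anova(np.array([1, 2, 3, 4.0]),
                             np.array(["a", "a", "b", "b"]))
        assert F == pytest.approx(8.0)
        assert p == pytest.approx(stats.f.sf(8.0, 1, 2))
        assert p == pytest.approx(0.105, abs=5e-3)

    def test_shift_invariance(self, rng):
        scores = rng.normal(size=20)
        labels = np.repeat(["a", "b"], 10)
        F1, _ = one_way_anova(scores, labels)
        F2, _ = one_way_anova(scores + 100.0, labels)
        assert F1 == pytest.approx(F2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            one_way_anova(np.arange(4.0), np.array(["a"] * 4))
        with pytest.raises(ValueError, match="within"):
            one_way_anova(np.array([1, 1, 2, 2.0]),
                          np.array(["a", "a", "b", "b"]))


class TestSynergyAssessment:
    def test_synergy_preset_verdict(self, synergy_design):
        score = composite_score(_animals("synergy", 2, synergy_design))
        out = synergy_assessment(score, synergy_design)
        hi = out[out["total"] == 25].iloc[0]
        assert hi["combination"] == "GBJ"
        assert hi["exceeds_all"]

    def test_additive_preset_rarely_synergistic(self, synergy_design):
        verdicts = []
        for seed in range(1, 21):
            score = composite_score(_animals("additive", seed, synergy_design))
            out = synergy_assessment(score, synergy_design)
            verdicts.append(bool(out["synergistic"].any()))
        assert sum(verdicts) <= 4  # not synergistic in >= 80% of seeds

    def test_missing_counterpart_group_rejected(self, synergy_design):
        score = composite_score(_animals("synergy", 2, synergy_design))
        score.groups = np.where(score.groups == "G@25", "QQ@25", score.groups)
        with pytest.raises(ValueError, match="missing counterpart"):
            synergy_assessment(score, synergy_design)

    def test_single_group_design_rejected(self, synergy_design):
        import synerfit.design as design_mod

        sub = synergy_design.table[synergy_design.table["label"] == "GBJ"].copy()
        d = design_mod.DesignTable(components=synergy_design.components, table=sub)
        score = composite_score(_animals("synergy", 2, synergy_design))
        with pytest.raises(ValueError, match="counterpart"):
            synergy_assessment(score, d)
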