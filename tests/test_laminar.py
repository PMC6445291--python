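"""Depth-binned model comparison, RM ANOVA, post-hocs and preference maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from laminar_encoding import laminar as lam
from laminar_encoding import synthetic_data as sd
from laminar_encoding.identification import fisher_transform


class TestSplitPac:
    def test_median_split_values(self):
        mrc = np.arange(1, 101, dtype=float)
        mask = lam.split_pac(mrc)
        assert mask.sum() == 50
        assert np.all(mrc[mask] >= 51)

    def test_all_equal_warns_first_half(self):
        with pytest.warns(UserWarning):
            mask = lam.split_pac(np.ones(6))
        np.testing.assert_array_equal(mask, [True, True, True, False, False, False])

    def test_matches_argsort_oracle(self):
        rng = np.random.default_rng(0)
        mrc = rng.standard_normal(101)
        mask = lam.split_pac(mrc)
        top = np.argsort(-mrc, kind="stable")[: len(mrc) // 2]
        expected = np.zeros(len(mrc), dtype=bool)
        expected[top] = True
        np.testing.assert_array_equal(mask, expected)

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError):
            lam.split_pac(np.array([np.nan, np.nan]))


def _tidy_scores(values):
    """values: dict (unit, region, depth, model) -> score."""
    return pd.DataFrame(
        [
            {"unit": u, "region": r, "depth": d, "model": m, "score": s}
            for (u, r, d, m), s in values.items()
        ]
    )


def _uniform_scores(n_units=4, score=0.7):
    out = {}
    for u in range(n_units):
        for r in ("PAC", "nonPAC"):
            for d in sd.DEPTHS:
                for m in ("frequency", "modulation"):
                    out[(u, r, float(d), m)] = score
    return out


class TestDepthBinScores:
    def test_uniform_scores(self):
        prof = lam.depth_bin_scores(_tidy_scores(_uniform_scores()))
        assert np.allclose(prof.table["mean"], 0.7)
        assert np.allclose(prof.difference["mean"], 0.0)

    def test_bins_partition_levels(self):
        assert sorted(sum(lam.DEPTH_BINS.values(), ())) == sorted(
            np.round(sd.DEPTHS, 1)
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        vals = _uniform_scores()
        vals = {k: rng.uniform(0.4, 0.9) for k in vals}
        df = _tidy_scores(vals)
        a = lam.depth_bin_scores(df)
        b = lam.depth_bin_scores(df.sample(frac=1.0, random_state=3))
        pd.testing.assert_frame_equal(
            a.table.reset_index(drop=True), b.table.reset_index(drop=True)
        )

    def test_empty_cell_named(self):
        df = _tidy_scores(_uniform_scores())
        df = df[~((df.region == "PAC") & (df.depth > 0.6))]
        with pytest.raises(ValueError, match="superficial"):
            lam.depth_bin_scores(df)

    def test_binned_means_match_level_means(self):
        rng = np.random.default_rng(2)
        vals = {k: rng.uniform(0.4, 0.9) for k in _uniform_scores()}
        prof = lam.depth_bin_scores(_tidy_scores(vals))
        manual = np.mean(
            [vals[(0, "PAC", d, "frequency")] for d in (0.1, 0.2, 0.3)]
        )
        cell = prof.per_unit[
            (prof.per_unit.unit == 0)
            & (prof.per_unit.region == "PAC")
            & (prof.per_unit.depth_bin == "deep")
            & (prof.per_unit.model == "frequency")
        ]["score"].iloc[0]
        assert cell == pytest.approx(manual)


def _anova_table(rng, n=12, effects=(0.0, 0.0, 0.0), noise=0.1):
    """units x 2 models x 3 depths scores around 0.7."""
    a_eff, b_eff, ab_eff = effects
    rows = []
    for u in range(n):
        base = 0.7 + rng.normal(0, 0.05)
        for mi, m in enumerate(("frequency", "modulation")):
            for bi, b in enumerate(lam.BIN_ORDER):
                mu = (
                    base
                    + a_eff * (mi - 0.5)
                    + b_eff * (bi - 1) / 2
                    + ab_eff * (mi - 0.5) * (bi - 1)
                )
                rows.append(
                    {
                        "unit": u,
                        "model": m,
                        "depth_bin": b,
                        "score": np.clip(mu + rng.normal(0, noise), 0.01, 0.99),
                    }
                )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_hand_decomposition(self):
        """Manual sums-of-squares on a small worked table."""
        rng = np.random.default_rng(3)
        df = _anova_table(rng, n=4)
        rep = lam.rm_anova_model_by_depth(df, fisher=False)

        y = np.empty((4, 2, 3))
        for ui in range(4):
            for mi, m in enumerate(("frequency", "modulation")):
                for bi, b in enumerate(lam.BIN_ORDER):
                    y[ui, mi, bi] = df[
                        (df.unit == ui) & (df.model == m) & (df.depth_bin == b)
                    ]["score"].iloc[0]
        m_all = y.mean()
        ss_a = 4 * 3 * sum((y[:, mi, :].mean() - m_all) ** 2 for mi in range(2))
        ss_as = 0.0
        for ui in range(4):
            for mi in range(2):
                ss_as += 3 * (
                    y[ui, mi, :].mean()
                    - y[:, mi, :].mean()
                    - y[ui].mean()
                    + m_all
                ) ** 2
        f_model = (ss_a / 1) / (ss_as / 3)
        assert rep.F("Model") == pytest.approx(f_model, rel=1e-10)
        assert rep.table.loc["Model", "df1"] == 1
        assert rep.table.loc["Model", "df2"] == 3
        assert rep.table.loc["Model x Depth", "df1"] == 2
        assert rep.table.loc["Model x Depth", "df2"] == 6

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = _anova_table(rng, n=8, effects=(0.05, 0.03, 0.02))
        rep = lam.rm_anova_model_by_depth(df, fisher=False)
        aov = pg.rm_anova(
            data=df, dv="score", within=["model", "depth_bin"], subject="unit",
            detailed=True,
        )
        aov = aov.set_index("Source")
        assert rep.F("Model") == pytest.approx(aov.loc["model", "F"], rel=1e-6)
        assert rep.F("Depth") == pytest.approx(aov.loc["depth_bin", "F"], rel=1e-6)
        assert rep.F("Model x Depth") == pytest.approx(
            aov.loc["model * depth_bin", "F"], rel=1e-6
        )

    def test_paper_style_degrees_of_freedom(self):
        rng = np.random.default_rng(5)
        rep = lam.rm_anova_model_by_depth(_anova_table(rng, n=12))
        assert rep.table.loc["Model", "df1"] == 1
        assert rep.table.loc["Model", "df2"] == 11
        assert rep.table.loc["Model x Depth", "df1"] == 2
        assert rep.table.loc["Model x Depth", "df2"] == 22

    def test_null_calibration(self):
        """Interaction rejection rate is ~alpha on pure-noise tables."""
        rng = np.random.default_rng(6)
        rej = 0
        n_rep = 500
        for _ in range(n_rep):
            rep = lam.rm_anova_model_by_depth(_anova_table(rng, n=12))
            rej += rep.p("Model x Depth") < 0.05
        assert abs(rej / n_rep - 0.05) < 0.02

    def test_additive_effect_no_interaction(self):
        rng = np.random.default_rng(7)
        model_sig = 0
        inter_sig = 0
        n_rep = 200
        for _ in range(n_rep):
            rep = lam.rm_anova_model_by_depth(
                _anova_table(rng, n=12, effects=(0.15, 0.0, 0.0), noise=0.05)
            )
            model_sig += rep.p("Model") < 0.05
            inter_sig += rep.p("Model x Depth") < 0.05
        assert model_sig / n_rep > 0.95
        assert abs(inter_sig / n_rep - 0.05) < 0.04

    def test_missing_cell_rejected(self):
        rng = np.random.default_rng(8)
        df = _anova_table(rng, n=4)
        with pytest.raises(ValueError):
            lam.rm_anova_model_by_depth(df.iloc[:-1])

    def test_too_few_units_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            lam.rm_anova_model_by_depth(_anova_table(rng, n=2))


class TestPosthocByDepth:
    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(10)
        df = _anova_table(rng, n=6)
        wide = df.pivot_table(index=["unit", "depth_bin"], columns="model",
                              values="score").reset_index()
        wide["modulation"] = wide["frequency"]
        equal = wide.melt(id_vars=["unit", "depth_bin"], var_name="model",
                          value_name="score")
        out = lam.posthoc_by_depth(equal)
        assert np.all(out["p_corrected"] == 1.0)

    def test_bonferroni_arithmetic(self):
        rng = np.random.default_rng(11)
        out = lam.posthoc_by_depth(
            _anova_table(rng, n=12, effects=(0.1, 0, 0), noise=0.05)
        )
        np.testing.assert_allclose(
            out["p_corrected"], np.minimum(1.0, out["p_raw"] * 3)
        )

    def test_superficial_only_advantage_detected(self):
        """Injected superficial-only modulation advantage (delta z = 1 sd,
        n = 12): superficial significant, deep/middle not, >= 90% of runs."""
        rng = np.random.default_rng(12)
        hit = 0
        n_rep = 200
        for _ in range(n_rep):
            rows = []
            for u in range(12):
                for b in lam.BIN_ORDER:
                    zf = rng.normal(0.5, 0.1)
                    zm = zf + (0.1 if b == "superficial" else 0.0) + rng.normal(0, 0.02)
                    for m, z in (("frequency", zf), ("modulation", zm)):
                        rows.append(
                            {"unit": u, "model": m, "depth_bin": b,
                             "score": (np.tanh(z) + 1) / 2}
                        )
            out = lam.posthoc_by_depth(pd.DataFrame(rows)).set_index("depth_bin")
            if (
                out.loc["superficial", "significant"]
                and not out.loc["deep", "significant"]
                and not out.loc["middle", "significant"]
            ):
                hit += 1
        assert hit / n_rep >= 0.90

    def test_single_unit_rejected(self):
        rng = np.random.default_rng(13)
        df = _anova_table(rng, n=1)
        with pytest.raises(ValueError):
            lam.posthoc_by_depth(df)


class TestPreferenceMaps:
    LABELS = {
        "bin_centers": np.geomspace(200, 6000, 8),
        "rates": np.array([1.0, 3.0, 9.0, 27.0]),
        "scales": np.array([0.5, 1.0, 2.0, 4.0]),
    }

    def test_single_nonzero_weight(self):
        w = np.zeros((128, 1))
        w[3 * 16 + 2 * 4 + 0] = 1.0  # bin 3, rate index 2 (9 Hz), scale 0.5
        pm = lam.build_preference_maps(w, self.LABELS)
        assert pm.best_frequency_hz[0] == self.LABELS["bin_centers"][3]
        assert pm.best_rate_hz[0] == 9.0
        assert pm.best_scale_cpo[0] == 0.5
        assert not pm.tie_flags[0]

    def test_uniform_weights_tie_lowest(self):
        pm = lam.build_preference_maps(np.ones((128, 2)), self.LABELS)
        assert pm.tie_flags.all()
        assert np.all(pm.best_rate_hz == 1.0)
        assert np.all(pm.best_scale_cpo == 0.5)
        assert np.all(pm.best_frequency_hz == self.LABELS["bin_centers"][0])

    def test_all_zero_undefined(self):
        pm = lam.build_preference_maps(np.zeros((128, 1)), self.LABELS)
        assert pm.undefined[0]
        assert np.isnan(pm.best_rate_hz[0])

    def test_tonotopic_gradient_recovered_from_true_weights(self):
        """The BF map built from the generator's true modulation weights
        follows the grid's tonotopic gradient (rank r > 0.9)."""
        pop, grid = sd.make_population(12, "default", seed=3)
        sel = pop.tuning_model == "modulation"
        pts = np.unique(pop.grid_index[sel])
        w = np.stack(
            [
                pop.true_weights[sel][pop.grid_index[sel] == g].mean(axis=0)
                for g in pts
            ],
            axis=1,
        )
        pm = lam.build_preference_maps(w, self.LABELS)
        rho = stats.spearmanr(pm.best_frequency_hz, grid.pref_octave[pts]).statistic
        assert rho > 0.9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lam.build_preference_maps(np.ones((100, 1)), self.LABELS)


class TestMapCorrelationTest:
    def test_identical_maps_degenerate(self):
        rng = np.random.default_rng(14)
        maps = rng.standard_normal((6, 30))
        out = lam.map_correlation_test(maps, maps.copy())
        assert out["degenerate"]
        assert np.allclose(out["per_unit_r"], 1.0)

    def test_negated_maps_r_minus_one(self):
        rng = np.random.default_rng(15)
        maps = rng.standard_normal((5, 30))
        out = lam.map_correlation_test(maps, -maps)
        assert np.allclose(out["per_unit_r"], -1.0)

    def test_per_unit_r_matches_pearson_oracle(self):
        rng = np.random.default_rng(16)
        a = rng.standard_normal((6, 40))
        b = 0.3 * a + rng.standard_normal((6, 40))
        out = lam.map_correlation_test(a, b)
        for u in range(6):
            assert out["per_unit_r"][u] == pytest.approx(
                stats.pearsonr(a[u], b[u]).statistic
            )
        assert not out["degenerate"]
        assert 0 <= out["p_value"] <= 1

    def test_median_map_min_units(self):
        a = np.full((5, 4), np.nan)
        a[:3, 0] = 1.0  # present in only 3 units < default 4
        a[:, 1] = 2.0
        b = np.zeros((5, 4))
        out = lam.map_correlation_test(a, b, min_units=4)
        assert np.isnan(out["median_map_a"][0])
        assert out["median_map_a"][1] == 2.0

    def test_signed_rank_detects_consistent_negative_r(self):
        rng = np.random.default_rng(17)
        a = rng.standard_normal((12, 60))
        b = -0.4 * a + rng.standard_normal((12, 60))
        out = lam.map_correlation_test(a, b)
        assert out["mean_r"] < 0
        assert out["p_value"] < 0.05

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            lam.map_correlation_test(np.ones((1, 5)), np.ones((1, 5)))


class TestGainInvariance:
    def test_depth_gain_leaves_scores_identical(self):
        """A depth-wise multiplicative gain applied to the measured
        responses (signal and noise together, both models alike) leaves
        every identification score — hence the model-difference depth
        profile — exactly unchanged.  This is the property that makes
        depth profiles of score differences interpretable despite the
        surface-weighted signal strength."""
        from laminar_encoding.identification import identification_scores

        rng = np.random.default_rng(18)
        s, v = 12, 30
        depth_gain = np.repeat([0.5, 1.0, 2.0, 4.0, 8.0, 16.0], 5)
        results = {}
        pred = {1: rng.standard_normal((s, v))}
        meas = {1: 0.8 * pred[1] + rng.standard_normal((s, v))}
        ids = {1: np.arange(s)}
        base = identification_scores(pred, meas, ids)
        gained = identification_scores(
            pred, {1: meas[1] * depth_gain}, ids
        )
        np.testing.assert_array_equal(base.scores, gained.scores)
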