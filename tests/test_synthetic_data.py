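"""Stimulus, design, population and forward-model generators."""

import numpy as np
import pytest

from laminar_encoding import audio_features as af
from laminar_encoding import synthetic_data as sd


class TestMakeSounds:
    def test_full_set_counts(self, full_sounds):
        assert full_sounds.n_sounds == 144
        cats, counts = np.unique(full_sounds.category, return_counts=True)
        assert len(cats) == 6
        assert np.all(counts == 24)
        assert full_sounds.waveforms.shape == (144, 16000)

    def test_rms_equalized(self, small_sounds):
        rms = np.sqrt((small_sounds.waveforms**2).mean(axis=1))
        assert np.allclose(rms, rms[0], rtol=1e-9)

    def test_single_sound_rms_target(self):
        s = sd.make_sounds(1, ["one"], seed=0, target_rms=0.07)
        assert s.n_sounds == 1
        np.testing.assert_allclose(np.sqrt((s.waveforms[0] ** 2).mean()), 0.07)

    def test_linear_onset_ramp(self, small_sounds):
        for wave in small_sounds.waveforms[:6]:
            assert wave[0] == 0.0
            peak = np.abs(wave).max()
            ramp = np.arange(160) / 160
            assert np.all(np.abs(wave[:160]) <= ramp * peak + 1e-12)
            assert np.all(np.abs(wave[-160:]) <= ramp[::-1] * peak + 1e-12)

    def test_duplicate_categories_rejected(self):
        with pytest.raises(ValueError):
            sd.make_sounds(2, ["a", "a"], seed=0)

    def test_invalid_duration_rejected(self):
        with pytest.raises(Exception):
            sd.make_sounds(1, ["a"], seed=0, duration_s=0.0)

    def test_categories_separate_in_modulation_space(self, small_sounds):
        """Category structure must be recoverable: within-category feature
        distances are smaller than between-category distances on average."""
        feats = af.build_feature_matrix(small_sounds, "modulation").values
        z = (feats - feats.mean(0)) / (feats.std(0) + 1e-12)
        cats = small_sounds.category
        d = np.linalg.norm(z[:, None, :] - z[None, :, :], axis=-1)
        same = cats[:, None] == cats[None, :]
        off = ~np.eye(len(cats), dtype=bool)
        assert d[same & off].mean() < d[~same].mean()


class TestSplitSets:
    def test_balanced_partition(self, full_sounds):
        for s in range(1, 5):
            sel = full_sounds.set_id == s
            assert sel.sum() == 36
            _, counts = np.unique(full_sounds.category[sel], return_counts=True)
            assert np.all(counts == 6)

    def test_single_set(self, small_sounds):
        one = sd.split_sets(small_sounds, 1, seed=0)
        assert np.all(one.set_id == 1)

    def test_seeds_give_different_balanced_partitions(self, small_sounds):
        a = sd.split_sets(small_sounds, 4, seed=1)
        b = sd.split_sets(small_sounds, 4, seed=2)
        assert not np.array_equal(a.set_id, b.set_id)
        for part in (a, b):
            for s in range(1, 5):
                _, counts = np.unique(
                    part.category[part.set_id == s], return_counts=True
                )
                assert np.all(counts == len(part.sound_id) // 4 // 6)

    def test_indivisible_counts_rejected(self):
        s = sd.make_sounds(3, ["a", "b"], seed=0)
        with pytest.raises(ValueError):
            sd.split_sets(s, 4, seed=0)


class TestMakeDesign:
    def test_every_sound_three_presentations(self, small_sounds, small_designs):
        counts = {int(s): 0 for s in small_sounds.sound_id}
        for d in small_designs:
            for s, sil, rep in zip(d.sound_id, d.is_silent, d.is_repeat):
                if not sil and not rep:
                    counts[int(s)] += 1
        assert set(counts.values()) == {3}

    def test_design_conservation(self, small_sounds, small_designs):
        total = sum(
            int((~d.is_silent & ~d.is_repeat).sum()) for d in small_designs
        )
        assert total == small_sounds.n_sounds * 3

    def test_isi_support(self, small_sounds):
        isis = set()
        for seed in range(25):
            for d in sd.make_design(small_sounds, runs=12, seed=seed):
                isis.update(int(i) for i in d.isis)
        assert isis == {2, 3, 4}

    def test_zero_runs_empty(self, small_sounds):
        assert sd.make_design(small_sounds, runs=0, seed=0) == []

    def test_silent_and_repeat_fractions(self, full_sounds):
        designs = sd.make_design(full_sounds, runs=12, seed=5)
        n_trials = sum(len(d.sound_id) for d in designs)
        sil = sum(int(d.is_silent.sum()) for d in designs)
        rep = sum(int(d.is_repeat.sum()) for d in designs)
        assert abs(sil / n_trials - 0.08) < 0.02
        assert abs(rep / n_trials - 0.06) < 0.02

    def test_repeats_follow_their_sound(self, full_sounds):
        for d in sd.make_design(full_sounds, runs=12, seed=6):
            for i in np.flatnonzero(d.is_repeat):
                j = i - 1
                while d.is_silent[j]:
                    j -= 1
                assert d.sound_id[i] == d.sound_id[j]

    def test_each_set_in_three_runs(self, small_designs):
        sets = [d.set_id for d in small_designs]
        _, counts = np.unique(sets, return_counts=True)
        assert np.all(counts == 3)

    def test_infeasible_run_volumes_rejected(self, small_sounds):
        with pytest.raises(sd.DesignError):
            sd.make_design(small_sounds, runs=12, seed=0, run_volumes=10)

    def test_runs_not_divisible_rejected(self, small_sounds):
        with pytest.raises(sd.DesignError):
            sd.make_design(small_sounds, runs=10, seed=0)


class TestMakePopulation:
    def test_pac_covers_half_the_grid(self):
        pop, grid = sd.make_population(10, "default", seed=7)
        assert grid.n_points == 20
        assert grid.pac_mask.sum() == 10
        assert pop.n_voxels == 20 * 9

    def test_snr_nondecreasing_with_depth(self):
        pop, grid = sd.make_population(5, "default", seed=7)
        for g in range(grid.n_points):
            snr = pop.snr[grid.voxel_index[g]]
            assert np.all(np.diff(snr) >= 0)

    def test_default_tuning_rule(self):
        pop, grid = sd.make_population(4, "default", seed=1)
        pac = pop.region == "PAC"
        deep_mid = pop.depth <= 0.6
        assert np.all(pop.tuning_model[pac & deep_mid] == "frequency")
        assert np.all(pop.tuning_model[pac & ~deep_mid] == "modulation")
        assert np.all(pop.tuning_model[~pac] == "modulation")

    def test_null_scenario_flat_frequency(self):
        pop, _ = sd.make_population(4, "null", seed=1)
        assert np.all(pop.tuning_model == "frequency")
        assert np.allclose(pop.snr, pop.snr[0])

    def test_gain_only_mixture_balanced_per_cell(self):
        pop, grid = sd.make_population(4, "gain_only", seed=1)
        for region in ("PAC", "nonPAC"):
            for d in range(1, 10):
                cell = (pop.region == region) & (pop.depth_index == d)
                frac = np.mean(pop.tuning_model[cell] == "frequency")
                assert 0.25 <= frac <= 0.75

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            sd.make_population(4, "nope", seed=1)

    def test_weights_unit_norm(self):
        pop, _ = sd.make_population(3, "default", seed=2)
        np.testing.assert_allclose(
            np.linalg.norm(pop.true_weights, axis=1), 1.0, rtol=1e-12
        )


def _one_voxel_population(hrf_peak=5.0, n_feat=4):
    w = np.zeros((1, n_feat))
    w[0, 0] = 1.0
    return sd.GroundTruthPopulation(
        grid_index=np.array([0]),
        depth_index=np.array([5]),
        depth=np.array([0.5]),
        region=np.array(["PAC"]),
        tuning_model=np.array(["frequency"]),
        true_weights=w,
        snr=np.array([2.0]),
        hrf_peak_s=np.array([hrf_peak]),
        hrf_undershoot=np.array([0.35]),
    )


def _one_sound_design(onset=3, n_vol=30):
    return [
        sd.EventDesign(
            run_id=1,
            set_id=1,
            onsets=np.array([onset]),
            sound_id=np.array([0]),
            is_silent=np.array([False]),
            is_repeat=np.array([False]),
            n_volumes=n_vol,
        )
    ]


class TestSimulateBold:
    def _features(self, n_feat=4):
        vals = np.array([[2.0, 0.0, 0.0, 0.0]])
        return af.FeatureMatrix(vals, "frequency", {}, np.array([0]))

    def test_noiseless_equals_direct_convolution(self):
        pop = _one_voxel_population()
        designs = _one_sound_design()
        fm = self._features()
        bold = sd.simulate_bold(pop, designs, fm, seed=0, noise_amp=0.0, drift_amp=0.0)
        kernel = sd.double_gamma_hrf(np.arange(13) * 2.4, 5.0, ratio=0.35)
        expected = np.zeros(30)
        amp = float(fm.values[0] @ pop.true_weights[0])
        expected[3 : 3 + 13] = amp * kernel
        np.testing.assert_allclose(bold.runs[0][:, 0], expected, atol=1e-12)

    def test_peak_volume_matches_hrf_latency(self):
        pop = _one_voxel_population(hrf_peak=6.0)
        bold = sd.simulate_bold(
            pop, _one_sound_design(onset=2), self._features(), seed=0,
            noise_amp=0.0, drift_amp=0.0,
        )
        kernel = sd.double_gamma_hrf(np.arange(13) * 2.4, 6.0, ratio=0.35)
        assert np.argmax(bold.runs[0][:, 0]) == 2 + np.argmax(kernel)

    def test_forward_model_linearity(self):
        pop = _one_voxel_population()
        pop2 = _one_voxel_population()
        pop2.true_weights = 2.0 * pop.true_weights
        designs = _one_sound_design()
        fm = self._features()
        a = sd.simulate_bold(pop, designs, fm, seed=0, noise_amp=0.0, drift_amp=0.0)
        b = sd.simulate_bold(pop2, designs, fm, seed=0, noise_amp=0.0, drift_amp=0.0)
        np.testing.assert_allclose(b.runs[0], 2.0 * a.runs[0], rtol=1e-10)

    def test_same_seed_bit_identical(self, small_sounds, small_designs):
        pop, _ = sd.make_population(2, "default", seed=4)
        feats = {
            t: af.build_feature_matrix(small_sounds, t)
            for t in ("frequency", "modulation")
        }
        a = sd.simulate_bold(pop, small_designs, feats, seed=9)
        b = sd.simulate_bold(pop, small_designs, feats, seed=9)
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra, rb)

    def test_silent_trials_are_baseline(self):
        pop = _one_voxel_population()
        designs = [
            sd.EventDesign(
                run_id=1, set_id=1,
                onsets=np.array([3, 8]),
                sound_id=np.array([0, sd.SILENT]),
                is_silent=np.array([False, True]),
                is_repeat=np.array([False, False]),
                n_volumes=40,
            )
        ]
        bold = sd.simulate_bold(
            pop, designs, self._features(), seed=0, noise_amp=0.0, drift_amp=0.0
        )
        only_sound = sd.simulate_bold(
            pop, _one_sound_design(onset=3, n_vol=40), self._features(), seed=0,
            noise_amp=0.0, drift_amp=0.0,
        )
        np.testing.assert_allclose(bold.runs[0], only_sound.runs[0], atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        pop = _one_voxel_population(n_feat=4)
        fm = af.FeatureMatrix(np.ones((1, 7)), "frequency", {}, np.array([0]))
        with pytest.raises(ValueError):
            sd.simulate_bold(pop, _one_sound_design(), fm, seed=0)
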