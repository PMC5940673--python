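"""Synthetic cohort generator: encoding model, trial/run simulation, behavior."""

import numpy as np
import pandas as pd
import pytest

from featuregain.cohort import (
    BehaviorParams,
    CohortConfig,
    ROISpec,
    SharpeningProfile,
    build_encoding_model,
    chance_level,
    generate_cohort,
    plan_test_sequences,
    plan_train_runs,
    recognition_fidelity,
    simulate_behavior,
    simulate_run,
    simulate_sequence_behavior,
    simulate_trial,
)
from featuregain.decoding import preprocess_run
from featuregain.errors import ConfigError, InvalidInputError

from conftest import tiny_cohort_config


class TestEncodingModel:
    def test_one_hot_layer_weights_touch_only_that_layer(self):
        roi = ROISpec("X", 50, (1.0, 0.0, 0.0))
        model = build_encoding_model(roi, [30, 20, 10], seed=0)
        assert set(model.weights) == {0}
        assert np.all(model.layer_assignment == 0)

    def test_same_seed_identical_weight_maps(self):
        roi = ROISpec("X", 40, (0.5, 0.5))
        a = build_encoding_model(roi, [25, 25], seed=3)
        b = build_encoding_model(roi, [25, 25], seed=3)
        assert np.array_equal(a.layer_assignment, b.layer_assignment)
        for l in a.weights:
            assert np.array_equal(a.weights[l], b.weights[l])

    def test_sparsity_fraction_within_binomial_bounds(self):
        roi = ROISpec("X", 500, (1.0,))
        model = build_encoding_model(roi, [1000], seed=1, sparsity=0.01)
        frac = np.mean(model.weights[0] != 0)
        assert 0.005 <= frac <= 0.02

    def test_every_voxel_has_a_nonzero_weight(self):
        roi = ROISpec("X", 200, (1.0,))
        model = build_encoding_model(roi, [400], seed=2, sparsity=0.002)
        assert np.all((model.weights[0] != 0).sum(axis=1) >= 1)


class TestSimulateTrial:
    @staticmethod
    def _setup(rng):
        roi = ROISpec("X", 30, (0.5, 0.5))
        model = build_encoding_model(roi, [12, 8], seed=0)
        stim = {"DNN1": rng.random(12), "DNN2": rng.random(8)}
        orig = {"DNN1": rng.random(12), "DNN2": rng.random(8)}
        return model, stim, orig

    def test_alpha_zero_noiseless_reproduces_stimulus_signal(self, rng):
        model, stim, orig = self._setup(rng)
        vols = simulate_trial(model, stim, orig, [0.0, 0.0], noise_sd=0.0, rng=rng)
        expected = model.signal_matrix({k: np.atleast_2d(v) for k, v in stim.items()})[0]
        assert vols.shape == (4, 30)
        for v in vols:
            assert np.allclose(v, expected, atol=1e-12)

    def test_alpha_one_noiseless_reproduces_original_signal(self, rng):
        model, stim, orig = self._setup(rng)
        vols = simulate_trial(model, stim, orig, [1.0, 1.0], noise_sd=0.0, rng=rng)
        expected = model.signal_matrix({k: np.atleast_2d(v) for k, v in orig.items()})[0]
        for v in vols:
            assert np.allclose(v, expected, atol=1e-12)

    def test_volume_average_noise_scales_as_sigma_over_two(self, rng):
        """Empirical SD of the 4-volume mean matches sigma/sqrt(4) within 2%."""
        model, stim, orig = self._setup(rng)
        sigma = 0.7
        means = []
        for _ in range(10000):
            vols = simulate_trial(model, stim, orig, [0.0, 0.0], noise_sd=sigma, rng=rng)
            means.append(vols.mean(axis=0))
        noise = np.asarray(means) - np.asarray(means).mean(axis=0)
        emp = noise.std()
        assert abs(emp - sigma / 2.0) / (sigma / 2.0) < 0.02

    def test_mismatched_feature_spaces_rejected(self, rng):
        model, stim, orig = self._setup(rng)
        with pytest.raises(InvalidInputError):
            simulate_trial(model, stim, {"DNN1": orig["DNN1"]}, [0, 0], 0.0, rng)


class TestSimulateRun:
    def test_zero_drift_zero_baseline_is_concatenation(self, rng):
        blocks = [rng.random((4, 6)) for _ in range(3)]
        run = simulate_run(blocks, drift_slope=0.0, baseline=0.0, shift_volumes=1)
        assert run.series.shape == (13, 6)
        assert np.array_equal(run.series[1:], np.vstack(blocks))
        assert run.boundaries == ((0, 4), (4, 8), (8, 12))

    def test_pure_drift_is_linear_per_voxel(self):
        blocks = [np.zeros((4, 3)) for _ in range(2)]
        run = simulate_run(blocks, drift_slope=0.5, baseline=np.array([1.0, 2.0, 3.0]))
        t = np.arange(run.series.shape[0])
        for v in range(3):
            assert np.allclose(run.series[:, v], [1.0, 2.0, 3.0][v] + 0.5 * t, atol=1e-12)

    def test_detrend_inverts_drift_and_baseline(self, rng):
        """Patterns from a drifting run equal patterns from the clean run."""
        blocks = [rng.random((4, 5)) for _ in range(4)]
        clean = simulate_run(blocks, 0.0, 0.0)
        dirty = simulate_run(blocks, drift_slope=0.03, baseline=rng.random(5))
        p_clean = preprocess_run(clean)
        p_dirty = preprocess_run(dirty)
        rms = np.sqrt(np.mean((p_clean - p_dirty) ** 2))
        assert rms < 1e-8

    def test_empty_run_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_run([], 0.0, 0.0)


class TestBehavior:
    def test_chance_levels(self):
        assert chance_level("category-prior") == pytest.approx(0.2)
        assert chance_level("no-prior") <= 0.05

    def test_random_guessing_with_prior_hits_20_percent(self, rng):
        params = BehaviorParams(slope=30.0, mid=0.45)
        hits = [
            simulate_behavior(0.0, "category-prior", params, rng)[0] for _ in range(20000)
        ]
        assert abs(np.mean(hits) - 0.2) < 0.015

    def test_full_fidelity_steep_slope_nearly_always_correct(self, rng):
        params = BehaviorParams(slope=20.0, mid=0.45)
        hits = [simulate_behavior(1.0, "no-prior", params, rng)[0] for _ in range(10000)]
        assert np.mean(hits) > 0.99

    def test_fidelity_monotone_in_blur_and_alpha(self):
        assert recognition_fidelity(0.0, 0.0) == 1.0
        assert recognition_fidelity(0.25, 0.0) < recognition_fidelity(0.12, 0.0)
        assert recognition_fidelity(0.25, 0.6) > recognition_fidelity(0.25, 0.0)

    def test_missing_response_imputation_rules(self, rng):
        params = BehaviorParams(p_missing=1.0, cert_slope=50.0, cert_mid=0.5)
        fids = [0.0, 0.4, 0.7, 1.0]
        _, certain = simulate_sequence_behavior(fids, "no-prior", params, rng)
        # all responses missing: first forced uncertain, last forced certain,
        # middle copies the previous (imputed) response
        assert certain[0] == 0
        assert certain[1] == 0 and certain[2] == 0
        assert certain[-1] == 1


class TestDesignPlans:
    def test_default_partition_20_runs_of_50(self):
        runs = plan_train_runs(CohortConfig())
        assert len(runs) == 20
        assert all(len(r) == 50 for r in runs)
        assert sorted(i for r in runs for i in r) == list(range(1000))

    def test_default_test_sequences_two_runs_of_40_per_condition(self):
        table = plan_test_sequences(CohortConfig(), master_seed=0)
        for cond in ("no-prior", "category-prior"):
            sub = table[table["condition"] == cond]
            assert len(sub) == 80
            assert sub.groupby("run").size().tolist() == [40, 40]

    def test_indivisible_partition_rejected(self):
        with pytest.raises(ConfigError) as err:
            CohortConfig(n_train_images=101).validate()
        assert any("train" in k for k in err.value.keys)


class TestGenerateCohort:
    def test_structure_and_ordering(self, tiny_cohort):
        cfg = tiny_cohort.config
        assert len(tiny_cohort.subjects) == cfg.n_subjects
        assert len(tiny_cohort.subjects[0].train_runs) == cfg.n_train_runs
        # each sequence runs strictly decreasing in blur, ending at 0
        for _, seq in tiny_cohort.test_meta.groupby("sequence_id"):
            blurs = seq.sort_values("trial")["blur"].tolist()
            assert blurs == sorted(blurs, reverse=True)
            assert blurs[-1] == 0.0

    def test_train_test_image_ids_disjoint(self, tiny_cohort):
        train_ids = set(tiny_cohort.train_meta["stimulus_id"])
        test_ids = set(tiny_cohort.test_meta["image_id"])
        assert train_ids.isdisjoint(test_ids)

    def test_zero_blur_renditions_match_original_features(self, tiny_cohort):
        meta = tiny_cohort.test_meta
        zero = meta.index[meta["blur"] == 0.0].to_numpy()
        for layer in tiny_cohort.layer_labels:
            assert np.array_equal(
                tiny_cohort.test_stim_features[layer][zero],
                tiny_cohort.test_orig_features[layer][zero],
            )

    def test_regeneration_is_bit_exact(self):
        cfg = tiny_cohort_config()
        a = generate_cohort(cfg, master_seed=99)
        b = generate_cohort(cfg, master_seed=99)
        assert np.array_equal(a.subjects[0].train_runs[0].series,
                              b.subjects[0].train_runs[0].series)
        assert np.array_equal(a.subjects[1].test_runs[0].series,
                              b.subjects[1].test_runs[0].series)
        pd.testing.assert_frame_equal(a.test_meta, b.test_meta)
        pd.testing.assert_frame_equal(a.subjects[0].behavior, b.subjects[0].behavior)

    def test_profile_recorded_as_ground_truth(self, tiny_cohort):
        assert tiny_cohort.profile == tiny_cohort.config.sharpening

    def test_composite_rois_are_member_unions(self):
        cfg = CohortConfig(
            n_subjects=1, n_train_images=40, train_run_size=40,
            n_test_sequences=2, test_runs_per_condition=1,
            network=tiny_cohort_config().network,
        )
        cohort = generate_cohort(cfg, master_seed=1)
        vox = cohort.roi_voxels
        assert np.array_equal(
            vox["LVC"], np.concatenate([vox["V1"], vox["V2"], vox["V3"]])
        )
        assert np.array_equal(
            vox["VC"],
            np.concatenate([vox[m] for m in ("V1", "V2", "V3", "V4", "LOC", "FFA", "PPA")]),
        )


class TestSharpeningProfile:
    def test_alpha_bounds_enforced(self):
        with pytest.raises(ConfigError):
            SharpeningProfile(no_prior=(1.2,), category_prior=(0.0,))

    def test_condition_lookup(self):
        p = SharpeningProfile.uniform(0.3, 2, prior_boost=0.2)
        assert np.allclose(p.alpha("no-prior"), [0.3, 0.3])
        assert np.allclose(p.alpha("category-prior"), [0.5, 0.5])
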