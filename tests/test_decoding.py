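"""Preprocessing, voxel selection, sparse regression, decoder training."""

import numpy as np
import pytest

from featuregain.cohort import simulate_run
from featuregain.decoding import (
    DecoderSet,
    Decoder,
    fit_sparse_regression,
    predict_features,
    preprocess_run,
    select_voxels,
    stimulus_patterns,
    train_decoders,
)
from featuregain.errors import InvalidInputError, SelectionError


class TestPreprocessRun:
    def test_pure_drift_yields_zero_patterns(self):
        n_vox = 5
        t = np.arange(17, dtype=float)
        series = 0.3 * t[:, None] + np.linspace(1, 2, n_vox)
        bounds = tuple((4 * i, 4 * i + 4) for i in range(4))
        patterns = preprocess_run(series, boundaries=bounds, shift_volumes=1)
        assert np.sqrt(np.mean(patterns**2)) < 1e-8

    def test_identical_volumes_yield_zscored_volume(self, rng):
        vols = rng.random((2, 6))
        series = np.vstack([np.zeros((1, 6))] + [np.tile(v, (4, 1)) for v in vols])
        bounds = ((0, 4), (4, 8))
        patterns = preprocess_run(series, boundaries=bounds, shift_volumes=1)
        data = np.repeat(vols, 4, axis=0)
        t = np.arange(8.0)
        tc = t - t.mean()
        slope = (tc @ data) / (tc @ tc)
        detr = data - data.mean(0) - np.outer(tc, slope)
        expected = detr / detr.std(0)
        assert np.allclose(patterns[0], expected[0:4].mean(0), atol=1e-10)
        assert np.allclose(patterns[1], expected[4:8].mean(0), atol=1e-10)

    def test_generator_round_trip(self, rng):
        """simulate_run -> preprocess_run recovers noise-free trial structure.

        Detrending also removes the signal's own chance linear component, so
        with many trials (where that component is small) the recovered
        patterns correlate near-perfectly with the injected signals, and the
        drift/baseline themselves are removed exactly (see the exact
        drift-invariance check in test_cohort).
        """
        signals = rng.standard_normal((50, 8))
        blocks = [np.tile(s, (4, 1)) for s in signals]
        run = simulate_run(blocks, drift_slope=0.02, baseline=rng.random(8))
        patterns = preprocess_run(run)
        rs = [np.corrcoef(patterns[:, v], signals[:, v])[0, 1] for v in range(8)]
        assert np.mean(rs) > 0.97
        assert min(rs) > 0.90

    def test_too_short_run_rejected(self):
        with pytest.raises(InvalidInputError):
            preprocess_run(np.zeros((1, 3)), boundaries=((0, 4),), shift_volumes=1)


class TestSelectVoxels:
    def test_k_at_least_voxel_count_selects_all(self, rng):
        X = rng.random((10, 7))
        idx = select_voxels(X, X[:, 3], k=100)
        assert len(idx) == 7
        assert idx[0] == 3

    def test_identical_voxel_ranks_first(self, rng):
        X = rng.standard_normal((30, 20))
        y = X[:, 11].copy()
        assert select_voxels(X, y, k=5)[0] == 11

    def test_planted_informative_voxels_recovered(self):
        """>= 9 of 10 informative voxels land in the top 10, in >= 95% of runs."""
        hits = 0
        reps = 40
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            n, n_info, n_noise = 200, 10, 200
            latent = rng.standard_normal(n)
            X = np.empty((n, n_info + n_noise))
            X[:, :n_info] = latent[:, None] + 0.4 * rng.standard_normal((n, n_info))
            X[:, n_info:] = rng.standard_normal((n, n_noise))
            y = latent + 0.2 * rng.standard_normal(n)
            top10 = select_voxels(X, y, k=10)
            if np.sum(top10 < n_info) >= 9:
                hits += 1
        assert hits / reps >= 0.95

    def test_negative_correlation_counts_unsigned(self, rng):
        X = rng.standard_normal((50, 10))
        y = -X[:, 4]
        assert select_voxels(X, y, k=1)[0] == 4
        assert select_voxels(X, y, k=1, signed_selection=True)[0] != 4

    def test_zero_variance_feature_rejected(self, rng):
        with pytest.raises(SelectionError):
            select_voxels(rng.random((10, 4)), np.ones(10), k=2)


class TestSparseRegression:
    def test_zero_target_gives_zero_model(self, rng):
        X = rng.standard_normal((40, 10))
        fit = fit_sparse_regression(X, np.zeros(40))
        assert np.all(fit.weights == 0.0)
        assert fit.intercept == 0.0

    def test_planted_sparse_recovery(self):
        """3 informative voxels of 50, noiseless: R^2 > 0.99 out of sample and
        >= 90% of the weight mass on the true voxels, across 20 seeds."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((300, 50))
            w = np.zeros(50)
            w[[3, 17, 40]] = [1.2, -0.8, 0.5]
            y = X @ w
            fit = fit_sparse_regression(X[:200], y[:200], tol=1e-6, max_iter=500)
            pred = X[200:] @ fit.weights + fit.intercept
            resid = y[200:] - pred
            r2 = 1.0 - resid @ resid / np.sum((y[200:] - y[200:].mean()) ** 2)
            mass = np.abs(fit.weights[[3, 17, 40]]).sum() / np.abs(fit.weights).sum()
            assert r2 > 0.99
            assert mass >= 0.9

    def test_matches_ols_on_full_rank_noise_free_data(self, rng):
        X = rng.standard_normal((100, 10))
        w = rng.standard_normal(10)
        y = X @ w
        fit = fit_sparse_regression(X, y, tol=1e-6, max_iter=500)
        pred = X @ fit.weights + fit.intercept
        rms = np.sqrt(np.mean((pred - y) ** 2))
        assert rms < 1e-6

    def test_pruned_weights_exactly_zero(self, rng):
        X = rng.standard_normal((150, 40))
        y = X[:, 0] + 0.1 * rng.standard_normal(150)
        fit = fit_sparse_regression(X, y, tol=1e-5, max_iter=300)
        pruned = ~np.isfinite(fit.alpha)
        assert np.any(pruned)
        assert np.all(fit.weights[pruned] == 0.0)

    def test_agreement_with_independent_ard_implementation(self, rng):
        """Cross-check against sklearn's ARD regression on noisy sparse data."""
        from sklearn.linear_model import ARDRegression

        X = rng.standard_normal((150, 30))
        w = np.zeros(30)
        w[[2, 9, 20]] = [1.0, -0.7, 0.4]
        y = X @ w + 0.3 * rng.standard_normal(150)
        ours = fit_sparse_regression(X, y, tol=1e-6, max_iter=500)
        theirs = ARDRegression(max_iter=500).fit(X, y)
        pred_ours = X @ ours.weights + ours.intercept
        r = np.corrcoef(pred_ours, theirs.predict(X))[0, 1]
        assert r > 0.999

    def test_ridge_fallback(self, rng):
        X = rng.standard_normal((60, 8))
        y = X[:, 1] + 0.05 * rng.standard_normal(60)
        fit = fit_sparse_regression(X, y, method="ridge", ridge_lambda=1.0)
        assert fit.converged
        assert np.argmax(np.abs(fit.weights)) == 1


class TestDecoderTraining:
    def test_disjoint_rois_train_independently(self, tiny_cohort):
        train, _ = stimulus_patterns(tiny_cohort, 0)
        feats = tiny_cohort.train_features
        units = {layer: np.arange(8) for layer in feats}  # fixed unit set
        both = train_decoders(
            {"LVC": train[:, tiny_cohort.roi_voxels["LVC"]],
             "HVC": train[:, tiny_cohort.roi_voxels["HVC"]]},
            feats, k_voxels=30, k_features=8, unit_indices=units,
            tol=1e-4, max_iter=100,
        )
        lvc_only = train_decoders(
            {"LVC": train[:, tiny_cohort.roi_voxels["LVC"]]},
            feats, k_voxels=30, k_features=8, unit_indices=units,
            tol=1e-4, max_iter=100,
        )
        for layer in both.feature_stats:
            for d_b, d_l in zip(both.models[("LVC", layer)], lvc_only.models[("LVC", layer)]):
                assert np.array_equal(d_b.weights, d_l.weights)
                assert np.array_equal(d_b.voxel_idx, d_l.voxel_idx)

    def test_recorded_stats_come_from_training_set_only(self, tiny_cohort):
        train, test = stimulus_patterns(tiny_cohort, 0)
        feats = tiny_cohort.train_features
        kwargs = dict(k_voxels=30, k_features=6, tol=1e-4, max_iter=80)
        d1 = train_decoders({"LVC": train[:, tiny_cohort.roi_voxels["LVC"]]}, feats, **kwargs)
        # feature SD recorded is that of the training features
        for layer, (idx, mean, sd) in d1.feature_stats.items():
            Y = feats[layer][:, idx]
            assert np.allclose(mean, Y.mean(0))
            assert np.allclose(sd, Y.std(0))
        # mutating test data cannot change anything: training never sees it
        d2 = train_decoders({"LVC": train[:, tiny_cohort.roi_voxels["LVC"]]}, feats, **kwargs)
        for layer in d1.feature_stats:
            for a, b in zip(d1.models[("LVC", layer)], d2.models[("LVC", layer)]):
                assert np.array_equal(a.weights, b.weights)


class TestPredictFeatures:
    @staticmethod
    def _manual_decoder_set(n_vox=4, sd=2.0, mean=5.0, weights=None):
        kept = np.arange(n_vox)
        roi_stats = {"R": (kept, np.zeros(n_vox), np.ones(n_vox))}
        feature_stats = {"L": (np.array([0]), np.array([mean]), np.array([sd]))}
        w = np.zeros(n_vox) if weights is None else weights
        ds = DecoderSet(roi_stats=roi_stats, feature_stats=feature_stats)
        ds.models[("R", "L")] = [Decoder(voxel_idx=kept, weights=w, intercept=0.0)]
        return ds

    def test_sd_only_denormalization_never_adds_mean(self, rng):
        ds = self._manual_decoder_set(sd=2.0, mean=5.0)
        out = predict_features(ds, {"R": rng.random((3, 4))})
        # zero weights -> normalized prediction 0 -> output 0, not the mean 5
        assert np.allclose(out[("R", "L")], 0.0)

    def test_doubling_recorded_sd_doubles_output(self, rng):
        w = rng.standard_normal(4)
        X = rng.random((5, 4))
        out1 = predict_features(self._manual_decoder_set(sd=2.0, weights=w), {"R": X})
        out2 = predict_features(self._manual_decoder_set(sd=4.0, weights=w), {"R": X})
        assert np.allclose(out2[("R", "L")], 2.0 * out1[("R", "L")])

    def test_voxel_count_mismatch_rejected(self, rng):
        ds = self._manual_decoder_set()
        with pytest.raises(InvalidInputError):
            predict_features(ds, {"R": rng.random((3, 2))})

    def test_exact_recovery_on_noiseless_invertible_data(self, rng):
        """Features encoded by an invertible linear map decode to > 0.999 corr."""
        n_train, n_test, n_units, n_vox = 120, 20, 6, 30
        Z = rng.standard_normal((n_train + n_test, n_units))
        W = rng.standard_normal((n_vox, n_units))
        X = Z @ W.T  # noiseless voxel patterns
        feats = {"L1": Z[:n_train]}
        ds = train_decoders({"R": X[:n_train]}, feats, k_voxels=n_vox,
                            k_features=n_units, tol=1e-8, max_iter=500)
        preds = predict_features(ds, {"R": X[n_train:]})[("R", "L1")]
        idx, mean, _ = ds.feature_stats["L1"]
        true_centered = Z[n_train:][:, idx] - mean
        for u in range(preds.shape[1]):
            r = np.corrcoef(preds[:, u], true_centered[:, u])[0, 1]
            assert r > 0.999


def test_decoding_accuracy_degrades_with_generator_noise():
    """Decoded-vs-true correlation falls monotonically over a 3-point noise grid."""
    from conftest import tiny_pipeline_config
    from featuregain.pipeline import run_in_memory
    import dataclasses

    rhos = []
    for noise in (0.5, 1.5, 4.0):
        cfg = tiny_pipeline_config(n_subjects=1)
        cfg.cohort = dataclasses.replace(cfg.cohort, noise_sd=noise)
        res = run_in_memory(cfg)
        rhos.append(res["audit"]["mean_rho_decoded"].mean())
    assert rhos[0] > rhos[1] > rhos[2]
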