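"""Pattern correlation, noise matching, feature gain, content specificity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from featuregain.errors import (
    InvalidInputError,
    MissingNoiseKeyError,
    NoiseMatchingError,
    UndefinedCorrelationError,
)
from featuregain.metrics import (
    compute_rs_ro,
    content_specificity,
    feature_gain,
    match_noise_sigma,
    noise_matched_delta,
    pattern_correlation,
)


class TestPatternCorrelation:
    def test_self_correlation_is_one(self, rng):
        v = rng.random(20)
        assert pattern_correlation(v, v) == pytest.approx(1.0)

    def test_negated_vector_gives_minus_one(self, rng):
        v = rng.random(20)
        assert pattern_correlation(v, -v) == pytest.approx(-1.0)

    def test_closed_form_arithmetic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 3.0, 5.0])
        # independent covariance/SD arithmetic
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        expected = cov / (a.std() * b.std())
        assert pattern_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    @given(
        n=st.integers(3, 60),
        scale_a=st.floats(0.01, 50.0),
        shift_a=st.floats(-10.0, 10.0),
        scale_b=st.floats(0.01, 50.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_affine_invariance_property(self, n, scale_a, shift_a, scale_b, seed):
        rng_ = np.random.default_rng(seed)
        a, b = rng_.standard_normal((2, n))
        r = pattern_correlation(a, b)
        assert pattern_correlation(scale_a * a + shift_a, b) == pytest.approx(r, abs=1e-9)
        assert pattern_correlation(a, scale_b * b - 7.0) == pytest.approx(r, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            pattern_correlation(np.ones(5), np.arange(5.0))

    def test_short_or_mismatched_vectors_rejected(self):
        with pytest.raises(InvalidInputError):
            pattern_correlation(np.arange(2.0), np.arange(2.0))
        with pytest.raises(InvalidInputError):
            pattern_correlation(np.arange(4.0), np.arange(5.0))


class TestComputeRsRo:
    def test_zero_blur_targets_identical(self, rng):
        pred = rng.random(15)
        target = rng.random(15)
        r_s, r_o, delta = compute_rs_ro(pred, target, target.copy())
        assert r_s == r_o
        assert delta == 0.0

    def test_perfect_prediction_of_original(self, rng):
        orig = rng.random(15)
        stim = rng.random(15)
        _, r_o, _ = compute_rs_ro(orig.copy(), stim, orig)
        assert r_o == pytest.approx(1.0)

    def test_feedforward_predictions_track_stimulus(self, rng):
        """alpha=0 noiseless linear readout: delta_decode <= 0 on average."""
        n_units, n_stim = 60, 120
        deltas = []
        for _ in range(n_stim):
            orig = rng.standard_normal(n_units)
            stim = 0.7 * orig + 0.7 * rng.standard_normal(n_units)  # blurred variant
            pred = stim + 0.3 * rng.standard_normal(n_units)  # decodes the stimulus
            _, _, d = compute_rs_ro(pred, stim, orig)
            deltas.append(d)
        assert np.mean(deltas) < 0.0
        assert np.mean(np.asarray(deltas) < 0) > 0.5  # sign test


class TestMatchNoiseSigma:
    def test_perfect_decoding_needs_no_noise(self, rng):
        true = rng.standard_normal((3, 50))
        match = match_noise_sigma(true.copy(), true)
        assert match.sigma == pytest.approx(0.0, abs=1e-9)

    def test_closed_form_at_rho_half(self, rng):
        """rho=0.5, unit SD -> sigma = sqrt(3); verified by Monte-Carlo."""
        k = 1000
        true = rng.standard_normal((1, k))
        true /= true.std(ddof=1)
        sigma_expected = np.sqrt(3.0)
        # build a prediction with corr ~0.5 and solve
        noisy_pred = true + sigma_expected * rng.standard_normal((1, k))
        match = match_noise_sigma(noisy_pred, true)
        assert match.sigma == pytest.approx(sigma_expected, rel=0.1)

        # Monte-Carlo verification of the closed form itself
        draws = true + sigma_expected * rng.standard_normal((200, k))
        rhos = [np.corrcoef(d, true[0])[0, 1] for d in draws]
        assert np.mean(rhos) == pytest.approx(0.5, abs=0.02)

    def test_matching_reproduces_decoded_correlation(self, rng):
        """End-to-end: noise calibrated from decoded 0%-blur correlations
        reproduces the mean decoded-vs-true correlation within 0.02.

        Uses 400-unit feature vectors; the per-image correlation estimates
        that drive the closed form are noisy, so the matching accuracy
        depends on the unit count (documented in the methods note).
        """
        k, m = 400, 25
        true = rng.standard_normal((m, k)) * rng.uniform(0.8, 1.2, size=(m, 1))
        pred = 0.8 * true + 1.0 * rng.standard_normal((m, k))
        match = match_noise_sigma(pred, true)
        noisy = noise_matched_delta(true, true, match.sigma, n_draws=100, rng=rng)
        mean_matched = noisy["r_s_noise"].mean()
        from featuregain.metrics import _rowwise_corr

        mean_decoded = _rowwise_corr(pred, true).mean()
        assert abs(mean_matched - mean_decoded) <= 0.02

    def test_low_correlation_stimuli_excluded(self, rng):
        true = rng.standard_normal((4, 100))
        pred = true.copy()
        pred[0] = rng.standard_normal(100)  # uncorrelated -> excluded
        match = match_noise_sigma(pred, true, rho_floor=0.05)
        assert match.n_excluded >= 1

    def test_all_excluded_raises(self, rng):
        true = rng.standard_normal((3, 100))
        pred = rng.standard_normal((3, 100))
        with pytest.raises(NoiseMatchingError):
            match_noise_sigma(pred, true, rho_floor=0.99)


class TestNoiseMatchedDelta:
    def test_sigma_zero_gives_perfect_stimulus_correlation(self, rng):
        stim = rng.standard_normal((5, 40))
        orig = 0.6 * stim + 0.8 * rng.standard_normal((5, 40))
        out = noise_matched_delta(stim, orig, sigma=0.0, n_draws=10, rng=rng)
        assert np.allclose(out["r_s_noise"], 1.0)
        assert np.all(out["delta_noise"] <= 0.0)

    def test_huge_sigma_drives_correlations_to_zero(self, rng):
        stim = rng.standard_normal((4, 500))
        orig = 0.5 * stim + rng.standard_normal((4, 500))
        s = stim.std()
        out = noise_matched_delta(stim, orig, sigma=100.0 * s, n_draws=200, rng=rng)
        assert np.all(np.abs(out["r_s_noise"]) < 0.05)
        assert np.all(np.abs(out["delta_noise"]) < 0.05)

    def test_delta_noise_negative_for_blurred_stimuli(self, rng):
        """Noisy stimulus features resemble the stimulus at least as much as
        the original, so delta_noise <= 0 on average (sign test)."""
        negatives = 0
        n_stim = 60
        for _ in range(n_stim):
            stim = rng.standard_normal((1, 80))
            orig = 0.7 * stim + 0.7 * rng.standard_normal((1, 80))
            out = noise_matched_delta(stim, orig, sigma=0.8, n_draws=50, rng=rng)
            negatives += int(out["delta_noise"].iloc[0] < 0)
        assert negatives > 0.9 * n_stim

    def test_invalid_arguments_rejected(self, rng):
        stim = rng.standard_normal((2, 10))
        with pytest.raises(InvalidInputError):
            noise_matched_delta(stim, stim, sigma=-1.0)
        with pytest.raises(InvalidInputError):
            noise_matched_delta(stim, stim, sigma=1.0, n_draws=0)


class TestFeatureGain:
    @staticmethod
    def _tables(delta_decode, delta_noise):
        corr = pd.DataFrame(
            {
                "subject": "S1", "roi": "VC", "layer": "DNN1",
                "trial": np.arange(len(delta_decode)),
                "blur": 0.25,
                "r_s": 0.5, "r_o": 0.5 + np.asarray(delta_decode),
                "delta_decode": delta_decode,
            }
        )
        noise = pd.DataFrame(
            {
                "subject": "S1", "roi": "VC", "layer": "DNN1",
                "trial": np.arange(len(delta_noise)),
                "r_s_noise": 0.5, "r_o_noise": 0.5 + np.asarray(delta_noise),
                "delta_noise": delta_noise,
            }
        )
        return corr, noise

    def test_equal_deltas_give_zero_gain(self):
        corr, noise = self._tables([-0.1, -0.2], [-0.1, -0.2])
        gain = feature_gain(corr, noise)
        assert np.allclose(gain["gain"], 0.0)

    def test_zero_blur_rows_excluded(self):
        corr, noise = self._tables([-0.1, -0.2], [-0.05, -0.1])
        corr.loc[1, "blur"] = 0.0
        gain = feature_gain(corr, noise)
        assert len(gain) == 1
        assert gain["gain"].iloc[0] == pytest.approx(-0.05)

    def test_missing_noise_key_raises(self):
        corr, noise = self._tables([-0.1, -0.2], [-0.05])
        with pytest.raises(MissingNoiseKeyError):
            feature_gain(corr, noise.iloc[:1])

    def test_antisymmetric_under_stimulus_original_swap(self, rng):
        """Swapping the stimulus/original roles in both branches negates gain."""
        pred = rng.standard_normal(50)
        stim = rng.standard_normal(50)
        orig = 0.5 * stim + rng.standard_normal(50)
        r_s, r_o, d_fwd = compute_rs_ro(pred, stim, orig)
        r_s2, r_o2, d_swp = compute_rs_ro(pred, orig, stim)
        assert d_swp == pytest.approx(-d_fwd, abs=1e-12)
        nd_fwd = noise_matched_delta(stim[None], orig[None], 0.5, n_draws=30,
                                     rng=np.random.default_rng(0))
        nd_swp = noise_matched_delta(stim[None], orig[None], 0.5, n_draws=30,
                                     rng=np.random.default_rng(0))
        # same draws: swapping the correlation targets negates the noise delta
        d1 = nd_fwd["r_o_noise"] - nd_fwd["r_s_noise"]
        d2 = nd_swp["r_s_noise"] - nd_swp["r_o_noise"]
        assert d2.iloc[0] == pytest.approx(-d1.iloc[0], abs=1e-12)


class TestContentSpecificity:
    def test_perfect_predictions_give_same_image_mean_one(self, rng):
        origs = rng.standard_normal((5, 40))
        idx = np.array([0, 1, 2, 3, 4])
        out = content_specificity(origs.copy(), origs, origs, idx)
        assert out["same_image_mean"] == pytest.approx(1.0)
        assert out["n_comparisons"] == 4

    def test_40_image_set_uses_39_comparisons(self, rng):
        origs = rng.standard_normal((40, 30))
        idx = np.arange(40)
        out = content_specificity(rng.standard_normal((40, 30)), origs, origs[idx], idx)
        assert out["n_comparisons"] == 39

    def test_single_image_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            content_specificity(rng.random((1, 10)), rng.random((1, 10)),
                                rng.random((1, 10)), np.array([0]))

    def test_informative_decoders_separate_same_from_different(self, tiny_analysis):
        content = tiny_analysis["content"]
        per_layer = content.groupby("layer")[
            ["same_image_mean", "different_image_mean"]
        ].mean()
        gap = per_layer["same_image_mean"] - per_layer["different_image_mean"]
        assert np.all(gap >= 0.1)


class TestCorrelationTableInvariants:
    def test_zero_blur_rows_have_equal_rs_ro(self, tiny_analysis):
        corr = tiny_analysis["corr_table"]
        zero = corr[corr["blur"] == 0.0]
        assert np.array_equal(zero["r_s"].to_numpy(), zero["r_o"].to_numpy())
        assert np.all(zero["delta_decode"] == 0.0)

    def test_correlations_within_bounds(self, tiny_analysis):
        corr = tiny_analysis["corr_table"]
        for col in ("r_s", "r_o"):
            assert corr[col].between(-1.0, 1.0).all()
        gain = tiny_analysis["gain_table"]
        assert gain["gain"].between(-2.0, 2.0).all()
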