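"""Pattern correlations, the noise-matched baseline and feature gain.

For each decoded feature vector the analysis computes its Pearson pattern
correlation with the true features of the blurred stimulus image (``r_s``)
and of the non-blurred original image (``r_o``); their difference
``delta_decode = r_o - r_s`` measures the bias of the decoded representation
toward the original.  Because a feedforward system with decoding noise also
produces a (negative) ``delta``, the baseline ``delta_noise`` is computed
from *noise-matched features*: true stimulus features plus Gaussian noise
whose level is calibrated so the noisy-vs-true correlation equals the
decoded-vs-true correlation for the non-blurred (0% blur) stimuli, where no
sharpening is assumed.  The sharpening statistic is

    feature gain = delta_decode - delta_noise

computed per stimulus and summarized with the 0% blur level excluded.

The matching noise level is solved in closed form: if a feature vector with
per-unit SD ``s`` receives i.i.d. Gaussian noise of SD ``sigma``, the
expected correlation with the clean vector is ``s / sqrt(s^2 + sigma^2)``,
so a target correlation ``rho`` gives ``sigma = s * sqrt(1/rho^2 - 1)``.
One sigma per stimulus is solved and the cell's sigma is the mean across
stimuli (per subject x ROI x layer); a pooled-correlation variant is
available behind ``pooled_rho``.

"True" feature vectors here are always train-mean-centered, matching the
SD-only denormalization of the decoder predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import substream
from .errors import (
    InvalidInputError,
    MissingNoiseKeyError,
    NoiseMatchingError,
    UndefinedCorrelationError,
)

__all__ = [
    "pattern_correlation",
    "compute_rs_ro",
    "build_correlation_table",
    "NoiseMatch",
    "match_noise_sigma",
    "noise_matched_delta",
    "build_noise_table",
    "feature_gain",
    "content_specificity",
    "analyze_cohort",
]


def pattern_correlation(a, b) -> float:
    """Pearson correlation of two feature vectors over their shared units."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise InvalidInputError("vectors must share a length of at least 3")
    ac = a - a.mean()
    bc = b - b.mean()
    na = float(ac @ ac)
    nb = float(bc @ bc)
    if na == 0.0 or nb == 0.0:
        raise UndefinedCorrelationError("correlation with a constant vector is undefined")
    return float((ac @ bc) / np.sqrt(na * nb))


def _rowwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of matching rows of two (n, k) matrices."""
    Ac = A - A.mean(axis=-1, keepdims=True)
    Bc = B - B.mean(axis=-1, keepdims=True)
    denom = np.sqrt((Ac**2).sum(-1) * (Bc**2).sum(-1))
    num = (Ac * Bc).sum(-1)
    out = np.zeros_like(num, dtype=float)
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def compute_rs_ro(predicted, true_stimulus, true_original) -> tuple[float, float, float]:
    """(r_s, r_o, delta_decode) for one decoded feature vector.

    All three vectors must cover the same selected units, with the true
    vectors train-mean-centered.  For a non-blurred stimulus the two targets
    are identical, so r_s == r_o exactly and delta_decode == 0.
    """
    r_s = pattern_correlation(predicted, true_stimulus)
    true_stimulus = np.asarray(true_stimulus, dtype=float)
    true_original = np.asarray(true_original, dtype=float)
    if np.array_equal(true_stimulus, true_original):
        r_o = r_s
    else:
        r_o = pattern_correlation(predicted, true_original)
    return r_s, r_o, r_o - r_s


def build_correlation_table(
    predictions: dict[tuple[str, str], np.ndarray],
    true_stim: dict[str, np.ndarray],
    true_orig: dict[str, np.ndarray],
    test_meta: pd.DataFrame,
    subject: str,
) -> pd.DataFrame:
    """Long-form r_s / r_o / delta_decode records for one subject.

    ``true_stim``/``true_orig`` map layer to train-mean-centered feature
    matrices over the selected units, aligned row-wise with ``test_meta``.
    """
    frames = []
    for (roi, layer), pred in predictions.items():
        stim = true_stim[layer]
        orig = true_orig[layer]
        r_s = _rowwise_corr(pred, stim)
        r_o = _rowwise_corr(pred, orig)
        zero = test_meta["blur"].to_numpy() == 0.0
        r_o = np.where(zero, r_s, r_o)  # identical targets at 0% blur
        df = test_meta.copy()
        df["subject"] = subject
        df["roi"] = roi
        df["layer"] = layer
        df["r_s"] = r_s
        df["r_o"] = r_o
        df["delta_decode"] = df["r_o"] - df["r_s"]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Noise matching
# ---------------------------------------------------------------------------


@dataclass
class NoiseMatch:
    """Matched noise level of one subject x ROI x layer cell."""

    sigma: float
    rhos: np.ndarray          # decoded-vs-true correlations of the 0% stimuli
    sigmas: np.ndarray        # per-stimulus closed-form solutions
    n_excluded: int


def match_noise_sigma(
    predicted_zero_blur: np.ndarray,
    true_features: np.ndarray,
    rho_floor: float = 0.05,
    pooled_rho: bool = False,
) -> NoiseMatch:
    """Gaussian noise SD matching decoded correlations at 0% blur.

    Per stimulus ``i`` with decoded-vs-true correlation ``rho_i`` and true
    feature SD ``s_i``, the closed form ``sigma_i = s_i * sqrt(1/rho_i^2 - 1)``
    makes ``corr(f + N(0, sigma_i^2), f)`` equal ``rho_i`` in expectation;
    the cell's sigma is the mean of ``sigma_i`` over stimuli (or, with
    ``pooled_rho``, the single solution at the pooled mean correlation).
    Stimuli with ``rho_i <= rho_floor`` are excluded; if all are excluded a
    :class:`NoiseMatchingError` is raised.
    """
    pred = np.atleast_2d(np.asarray(predicted_zero_blur, dtype=float))
    true = np.atleast_2d(np.asarray(true_features, dtype=float))
    if pred.shape != true.shape or pred.shape[0] < 1:
        raise InvalidInputError("need matching (n_stimuli, n_units) matrices")
    rhos = _rowwise_corr(pred, true)
    s = true.std(axis=1, ddof=1)
    ok = rhos > rho_floor
    n_excluded = int((~ok).sum())
    if not np.any(ok):
        raise NoiseMatchingError(
            f"all {len(rhos)} stimuli fell at or below the correlation floor {rho_floor}"
        )
    if pooled_rho:
        rho_bar = float(rhos[ok].mean())
        sigma = float(s[ok].mean() * np.sqrt(1.0 / rho_bar**2 - 1.0))
        sigmas = np.full(int(ok.sum()), sigma)
    else:
        sigmas = s[ok] * np.sqrt(1.0 / np.clip(rhos[ok], 1e-12, 1.0) ** 2 - 1.0)
        sigma = float(sigmas.mean())
    return NoiseMatch(sigma=sigma, rhos=rhos, sigmas=np.asarray(sigmas), n_excluded=n_excluded)


def noise_matched_delta(
    true_stim: np.ndarray,
    true_orig: np.ndarray,
    sigma: float,
    n_draws: int = 100,
    rng: np.random.Generator | int | None = 0,
) -> pd.DataFrame:
    """Monte-Carlo r_s_noise / r_o_noise / delta_noise per stimulus.

    Noisy features are the true stimulus features plus i.i.d. Gaussian noise
    of SD ``sigma`` per unit; correlations are averaged over ``n_draws``
    seeded draws to reduce Monte-Carlo variance.
    """
    if sigma < 0:
        raise InvalidInputError("sigma must be >= 0")
    if n_draws < 1:
        raise InvalidInputError("n_draws must be >= 1")
    stim = np.atleast_2d(np.asarray(true_stim, dtype=float))
    orig = np.atleast_2d(np.asarray(true_orig, dtype=float))
    if stim.shape != orig.shape:
        raise InvalidInputError("stimulus/original feature shapes differ")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m, k = stim.shape
    if sigma == 0.0:
        r_s = np.ones(m)
        r_o = _rowwise_corr(stim, orig)
    else:
        r_s = np.zeros(m)
        r_o = np.zeros(m)
        # chunk draws to bound memory at ~ (chunk, m, k) doubles
        chunk = max(1, int(2e6 // max(m * k, 1)))
        done = 0
        while done < n_draws:
            c = min(chunk, n_draws - done)
            noisy = stim[None, :, :] + rng.standard_normal((c, m, k)) * sigma
            r_s += _rowwise_corr(noisy, np.broadcast_to(stim, noisy.shape)).sum(axis=0)
            r_o += _rowwise_corr(noisy, np.broadcast_to(orig, noisy.shape)).sum(axis=0)
            done += c
        r_s /= n_draws
        r_o /= n_draws
    return pd.DataFrame(
        {"r_s_noise": r_s, "r_o_noise": r_o, "delta_noise": r_o - r_s}
    )


def build_noise_table(
    corr_table: pd.DataFrame,
    true_stim: dict[str, np.ndarray],
    true_orig: dict[str, np.ndarray],
    test_meta: pd.DataFrame,
    n_draws: int = 100,
    rho_floor: float = 0.05,
    pooled_rho: bool = False,
    seed: int = 0,
    predictions: dict[tuple[str, str], np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise-matched baseline rows for every (subject, roi, layer) cell.

    Returns ``(noise_table, audit)`` where ``noise_table`` has one row per
    trial per cell with r_s_noise/r_o_noise/delta_noise and ``audit`` has one
    row per cell with the matched sigma, the mean decoded and mean
    noise-matched 0%-blur correlations (the matching check) and the number
    of excluded stimuli.

    ``predictions`` is required to recompute the 0%-blur decoded
    correlations; cells are keyed exactly as in ``corr_table``.
    """
    if predictions is None:
        raise InvalidInputError("predictions are required for noise matching")
    zero_rows = test_meta.index[test_meta["blur"] == 0.0].to_numpy()
    noise_frames = []
    audit_rows = []
    subject = corr_table["subject"].iloc[0] if len(corr_table) else ""
    for (roi, layer), pred in predictions.items():
        stim = true_stim[layer]
        orig = true_orig[layer]
        match = match_noise_sigma(
            pred[zero_rows], stim[zero_rows], rho_floor=rho_floor, pooled_rho=pooled_rho
        )
        rng = substream(seed, "noise-draws", subject, roi, layer)
        nd = noise_matched_delta(stim, orig, match.sigma, n_draws=n_draws, rng=rng)
        nd["trial"] = test_meta["trial"].to_numpy()
        nd["subject"] = subject
        nd["roi"] = roi
        nd["layer"] = layer
        noise_frames.append(nd)
        audit_rows.append(
            {
                "subject": subject,
                "roi": roi,
                "layer": layer,
                "sigma": match.sigma,
                "n_excluded": match.n_excluded,
                "mean_rho_decoded": float(match.rhos[match.rhos > rho_floor].mean()),
                "mean_rho_matched": float(nd.loc[np.isin(nd["trial"],
                    test_meta.loc[zero_rows, "trial"]), "r_s_noise"].mean()),
            }
        )
    return pd.concat(noise_frames, ignore_index=True), pd.DataFrame(audit_rows)


def feature_gain(corr_table: pd.DataFrame, noise_table: pd.DataFrame) -> pd.DataFrame:
    """Per-stimulus feature gain = delta_decode - delta_noise.

    Joined on (subject, roi, layer, trial); rows at 0% blur are excluded
    from the gain table (they define the baseline, not the statistic).
    A record with no matching noise row raises :class:`MissingNoiseKeyError`.
    """
    keys = ["subject", "roi", "layer", "trial"]
    blurred = corr_table[corr_table["blur"] > 0.0]
    merged = blurred.merge(
        noise_table[keys + ["r_s_noise", "r_o_noise", "delta_noise"]],
        on=keys, how="left",
    )
    if merged["delta_noise"].isna().any():
        missing = merged.loc[merged["delta_noise"].isna(), keys].iloc[0].tolist()
        raise MissingNoiseKeyError(f"no noise baseline for record {missing}")
    merged["gain"] = merged["delta_decode"] - merged["delta_noise"]
    return merged


def content_specificity(
    predicted: np.ndarray,
    true_orig_by_image: np.ndarray,
    true_stim: np.ndarray,
    image_index: np.ndarray,
) -> dict[str, float]:
    """Same-image vs different-image correlation of decoded features.

    ``predicted``/``true_stim`` are (n_trials, k) over blurred trials only;
    ``true_orig_by_image`` is (n_images, k) with one row per distinct test
    image and ``image_index`` maps each trial to its image row.  Returns the
    same-image mean, the different-image mean (each trial compared against
    the n_images - 1 noncorresponding originals), the true-feature baseline
    (stimulus features against noncorresponding originals) and the
    comparison count.
    """
    pred = np.atleast_2d(np.asarray(predicted, dtype=float))
    origs = np.atleast_2d(np.asarray(true_orig_by_image, dtype=float))
    stim = np.atleast_2d(np.asarray(true_stim, dtype=float))
    idx = np.asarray(image_index, dtype=int)
    n_images = origs.shape[0]
    if n_images < 2:
        raise InvalidInputError("content specificity needs at least two test images")
    if pred.shape[0] != idx.shape[0] or stim.shape != pred.shape:
        raise InvalidInputError("trial rows and image indices must align")

    def cross_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
        Ac = A - A.mean(1, keepdims=True)
        Bc = B - B.mean(1, keepdims=True)
        Ac /= np.sqrt((Ac**2).sum(1, keepdims=True))
        Bc /= np.sqrt((Bc**2).sum(1, keepdims=True))
        return Ac @ Bc.T

    C = cross_corr(pred, origs)  # (n_trials, n_images)
    same = C[np.arange(len(idx)), idx]
    diff = (C.sum(axis=1) - same) / (n_images - 1)
    Ct = cross_corr(stim, origs)
    same_t = Ct[np.arange(len(idx)), idx]
    baseline = (Ct.sum(axis=1) - same_t) / (n_images - 1)
    return {
        "same_image_mean": float(same.mean()),
        "different_image_mean": float(diff.mean()),
        "true_feature_baseline": float(baseline.mean()),
        "n_comparisons": n_images - 1,
    }


# ---------------------------------------------------------------------------
# Cohort-level driver
# ---------------------------------------------------------------------------


def analyze_cohort(
    cohort,
    decoders_by_subject: list,
    predictions_by_subject: list[dict[tuple[str, str], np.ndarray]],
    n_draws: int = 100,
    rho_floor: float = 0.05,
    pooled_rho: bool = False,
    seed: int = 0,
    content_roi: str | None = None,
) -> dict:
    """Run the full correlation / noise-matching / gain analysis.

    Returns a dict with ``corr_table``, ``noise_table``, ``gain_table``,
    ``audit`` (matched sigmas and the 0%-blur matching check) and
    ``content`` (content-specificity summary per layer for ``content_roi``,
    defaulting to the first decoded ROI).
    """
    corr_frames, noise_frames, audit_frames, gain_frames = [], [], [], []
    content_rows = []
    for s, (decoders, predictions) in enumerate(
        zip(decoders_by_subject, predictions_by_subject)
    ):
        subject = cohort.subjects[s].spec.subject_id
        meta = cohort.subject_test_meta(s)
        true_stim = {}
        true_orig = {}
        for layer, (unit_idx, fmean, _fsd) in decoders.feature_stats.items():
            true_stim[layer] = cohort.test_stim_features[layer][:, unit_idx] - fmean
            true_orig[layer] = cohort.test_orig_features[layer][:, unit_idx] - fmean
        corr = build_correlation_table(predictions, true_stim, true_orig, meta, subject)
        noise, audit = build_noise_table(
            corr, true_stim, true_orig, meta,
            n_draws=n_draws, rho_floor=rho_floor, pooled_rho=pooled_rho,
            seed=seed, predictions=predictions,
        )
        gain = feature_gain(corr, noise)
        corr_frames.append(corr)
        noise_frames.append(noise)
        audit_frames.append(audit)
        gain_frames.append(gain)

        roi_for_content = content_roi or next(iter(predictions))[0]
        blurred = meta["blur"].to_numpy() > 0.0
        image_ids = meta["image_id"].to_numpy()
        unique_images, img_idx = np.unique(image_ids, return_inverse=True)
        zero = np.flatnonzero(meta["blur"].to_numpy() == 0.0)
        for layer in decoders.feature_stats:
            if (roi_for_content, layer) not in predictions:
                continue
            orig_rows = {img_idx[t]: t for t in zero}
            origs = np.vstack(
                [true_orig[layer][orig_rows[i]] for i in range(len(unique_images))]
            )
            cs = content_specificity(
                predictions[(roi_for_content, layer)][blurred],
                origs,
                true_stim[layer][blurred],
                img_idx[blurred],
            )
            cs.update({"subject": subject, "roi": roi_for_content, "layer": layer})
            content_rows.append(cs)

    return {
        "corr_table": pd.concat(corr_frames, ignore_index=True),
        "noise_table": pd.concat(noise_frames, ignore_index=True),
        "gain_table": pd.concat(gain_frames, ignore_index=True),
        "audit": pd.concat(audit_frames, ignore_index=True),
        "content": pd.DataFrame(content_rows),
    }
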