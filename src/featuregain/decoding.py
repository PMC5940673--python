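"""Run preprocessing and per-feature sparse linear decoders.

The preprocessing convention follows the block-averaging protocol: volumes
are shifted by one volume to compensate for the hemodynamic delay, each run
is detrended per voxel by least squares, z-scored per voxel within the run,
and the four volumes of each stimulus block are averaged into a single
pattern.

Decoding follows the train-only normalization protocol exactly: training
patterns and features are z-scored with recorded means/SDs, test patterns
are normalized with the *recorded training* statistics, and predictions are
denormalized by multiplying with the training feature SD only - the training
mean is never added back, so predicted features live in train-mean-centered
space and must be correlated against train-mean-centered "true" features.

The per-feature decoder is a sparse (automatic relevance determination)
linear regression: one precision hyperparameter per weight, updated by
evidence approximation, with voxels pruned to exactly zero weight once their
precision exceeds a threshold.  A ridge fallback is selectable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np

from .errors import InvalidInputError, SelectionError
from .network import select_feature_units

__all__ = [
    "preprocess_run",
    "stimulus_patterns",
    "crossval_unit_scores",
    "select_voxels",
    "SLRFit",
    "fit_sparse_regression",
    "Decoder",
    "DecoderSet",
    "train_decoders",
    "predict_features",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def preprocess_run(run, boundaries=None, shift_volumes: int | None = None) -> np.ndarray:
    """Shift, detrend, z-score a run and average each trial's volumes.

    ``run`` is a ``RunData`` or a plain ``(T, n_voxels)`` array (in which
    case ``boundaries`` and ``shift_volumes`` must be given).  Boundaries are
    trial windows in post-shift coordinates.  Returns ``(n_trials, n_voxels)``
    patterns.
    """
    if hasattr(run, "series"):
        series = np.asarray(run.series, dtype=float)
        boundaries = run.boundaries if boundaries is None else boundaries
        shift = run.shift_volumes if shift_volumes is None else shift_volumes
    else:
        series = np.asarray(run, dtype=float)
        if boundaries is None or shift_volumes is None:
            raise InvalidInputError("plain arrays need boundaries and shift_volumes")
        shift = shift_volumes
    if series.ndim != 2:
        raise InvalidInputError("run series must be 2-D (time x voxels)")
    if series.shape[0] <= shift:
        raise InvalidInputError("run too short after volume shift")
    data = series[shift:]
    t_end = max(b for _, b in boundaries)
    if t_end > data.shape[0]:
        raise InvalidInputError("trial boundaries exceed the shifted run length")

    # least-squares linear detrend (slope + intercept) per voxel
    t = np.arange(data.shape[0], dtype=float)
    tc = t - t.mean()
    denom = float(tc @ tc)
    slope = (tc @ data) / denom if denom > 0 else np.zeros(data.shape[1])
    data = data - data.mean(axis=0) - np.outer(tc, slope)

    sd = data.std(axis=0)
    # scale-aware zero-variance floor: a voxel whose residual is numerical
    # noise after detrending stays identically 0 instead of amplifying it
    floor = 1e-10 * max(1.0, float(np.abs(series).max()))
    nonzero = sd > floor
    data[:, ~nonzero] = 0.0
    data[:, nonzero] /= sd[nonzero]

    return np.vstack([data[a:b].mean(axis=0) for a, b in boundaries])


def stimulus_patterns(cohort, subject_index: int) -> tuple[np.ndarray, np.ndarray]:
    """Preprocess all runs of one subject into (train, test) pattern matrices.

    Rows follow ``cohort.train_meta`` / ``cohort.test_meta`` order.
    """
    subject = cohort.subjects[subject_index]
    train = np.vstack([preprocess_run(r) for r in subject.train_runs])
    test = np.vstack([preprocess_run(r) for r in subject.test_runs])
    return train, test


# ---------------------------------------------------------------------------
# Unit decodability screening (for feature-unit selection)
# ---------------------------------------------------------------------------


def crossval_unit_scores(
    train_patterns: np.ndarray,
    train_features: np.ndarray,
    ridge_lambda: float = 100.0,
    n_folds: int = 2,
) -> np.ndarray:
    """Cross-validated decodability score per feature unit.

    Deterministic interleaved folds; within each fold, a ridge decoder for
    all units at once (via SVD of the fold-train patterns) predicts the
    held-out features, and the score is the mean held-out Pearson correlation
    per unit.  Zero-variance units score 0.
    """
    X = np.asarray(train_patterns, dtype=float)
    Y = np.asarray(train_features, dtype=float)
    n = X.shape[0]
    if n < 2 * n_folds:
        raise InvalidInputError("too few training samples for cross-validation")
    scores = np.zeros((n_folds, Y.shape[1]))
    for f in range(n_folds):
        test_mask = (np.arange(n) % n_folds) == f
        Xtr, Xte = X[~test_mask], X[test_mask]
        Ytr, Yte = Y[~test_mask], Y[test_mask]
        xm, xs = Xtr.mean(0), np.maximum(Xtr.std(0), 1e-12)
        ym = Ytr.mean(0)
        Xtr_n = (Xtr - xm) / xs
        Xte_n = (Xte - xm) / xs
        U, S, Vt = np.linalg.svd(Xtr_n, full_matrices=False)
        shrink = S / (S**2 + ridge_lambda)
        pred = Xte_n @ (Vt.T * shrink) @ (U.T @ (Ytr - ym))
        scores[f] = _columnwise_corr(pred, Yte - ym)
    return scores.mean(axis=0)


def _columnwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(0)
    Bc = B - B.mean(0)
    denom = np.sqrt((Ac**2).sum(0) * (Bc**2).sum(0))
    num = (Ac * Bc).sum(0)
    out = np.zeros(A.shape[1])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


# ---------------------------------------------------------------------------
# Voxel selection
# ---------------------------------------------------------------------------


def select_voxels(
    train_patterns: np.ndarray,
    feature_values: np.ndarray,
    k: int = 500,
    signed_selection: bool = False,
) -> np.ndarray:
    """Indices of the ``k`` voxels most correlated with one feature.

    Ranking uses the absolute Pearson correlation by default (a negatively
    correlated voxel is equally informative for a linear decoder);
    ``signed_selection=True`` restores positive-only ranking.  Ties break by
    ascending index; ``k`` is capped at the voxel count.
    """
    X = np.asarray(train_patterns, dtype=float)
    y = np.asarray(feature_values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("need >= 2 training samples with matching shapes")
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y == 0.0:
        raise SelectionError("feature has zero variance on the training set")
    Xc = X - X.mean(0)
    denom = np.sqrt((Xc**2).sum(0) * ss_y)
    r = np.zeros(X.shape[1])
    ok = denom > 0
    r[ok] = (Xc.T @ yc)[ok] / denom[ok]
    key = r if signed_selection else np.abs(r)
    order = np.lexsort((np.arange(X.shape[1]), -key))
    return order[: min(k, X.shape[1])]


# ---------------------------------------------------------------------------
# Sparse (ARD) linear regression
# ---------------------------------------------------------------------------


@dataclass
class SLRFit:
    """Result of one sparse-regression fit.

    ``weights`` has one entry per input column; pruned columns are exactly 0.
    ``alpha`` holds the per-weight precisions (``inf`` for pruned weights).
    """

    weights: np.ndarray
    intercept: float
    alpha: np.ndarray
    beta: float
    n_iter: int
    converged: bool


def fit_sparse_regression(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 500,
    prune_threshold: float = 1e8,
    method: str = "ard",
    ridge_lambda: float = 10.0,
    gram: np.ndarray | None = None,
) -> SLRFit:
    """Automatic-relevance-determination linear regression (ridge selectable).

    Evidence-approximation updates: with per-weight precisions ``alpha`` and
    noise precision ``beta``, the posterior is
    ``Sigma = (diag(alpha) + beta X'X)^-1``, ``m = beta Sigma X'y``; each
    iteration sets ``gamma_j = 1 - alpha_j Sigma_jj``,
    ``alpha_j <- gamma_j / m_j^2`` and ``beta <- (n - sum gamma) / RSS``.
    Weights whose precision exceeds ``prune_threshold`` are pruned to exact
    zero.  Convergence: max absolute change of the posterior weights and
    relative change of the noise precision both < ``tol`` (the precisions of
    irrelevant weights grow without bound until they hit the pruning cap, so
    a weight-space criterion is the one that can actually be met);
    non-convergence returns the best (last) iterate with ``converged=False``
    and a logged warning.

    ``gram`` optionally supplies the precomputed centered Gram matrix
    ``Xc' Xc`` (a speed hook for callers fitting many features on subsets of
    one pattern matrix); it must match the centered ``X``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("X must be 2-D with rows matching y")
    n, p = X.shape
    xm = X.mean(0)
    ym = float(y.mean())
    Xc = X - xm
    yc = y - ym
    yy = float(yc @ yc)

    if yy == 0.0 or p == 0:
        return SLRFit(
            weights=np.zeros(p), intercept=ym, alpha=np.full(p, np.inf),
            beta=np.inf, n_iter=0, converged=True,
        )

    G = (Xc.T @ Xc) if gram is None else np.asarray(gram, dtype=float)
    g = Xc.T @ yc

    if method == "ridge":
        w = np.linalg.solve(G + ridge_lambda * np.eye(p), g)
        rss = max(yy - 2 * w @ g + w @ G @ w, 1e-12)
        return SLRFit(
            weights=w, intercept=ym - xm @ w, alpha=np.full(p, ridge_lambda),
            beta=n / rss, n_iter=1, converged=True,
        )
    if method != "ard":
        raise InvalidInputError(f"unknown method {method!r}")

    alpha = np.full(p, 1.0)
    beta = float(n / yy)
    active = np.ones(p, dtype=bool)
    m_full = np.zeros(p)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            m_full[:] = 0.0
            converged = True
            break
        Ga = G[np.ix_(idx, idx)]
        ga = g[idx]
        H = beta * Ga + np.diag(alpha[idx])
        jitter = 1e-12 * float(np.trace(H)) / idx.size
        for _attempt in range(12):
            try:
                L = np.linalg.cholesky(H)
                break
            except np.linalg.LinAlgError:
                H = H + jitter * np.eye(idx.size)
                jitter *= 10.0
        else:  # pragma: no cover - pathological conditioning
            raise np.linalg.LinAlgError("ARD normal equations irreparably singular")
        Linv = np.linalg.inv(L)  # Sigma = Linv' Linv
        sigma_diag = (Linv**2).sum(axis=0)
        m = beta * (Linv.T @ (Linv @ ga))
        gamma = 1.0 - alpha[idx] * sigma_diag
        gamma = np.clip(gamma, 1e-12, None)
        rss = max(yy - 2.0 * m @ ga + m @ Ga @ m, 1e-12)
        beta_new = float(np.clip((n - gamma.sum()) / rss, 1e-12, 1e12))
        alpha_new = gamma / np.maximum(m**2, 1e-300)
        alpha_new = np.clip(alpha_new, 1e-12, 10 * prune_threshold)

        m_new = np.zeros(p)
        m_new[idx] = np.where(alpha_new > prune_threshold, 0.0, m)
        rel = max(float(np.max(np.abs(m_new - m_full))), abs(beta_new - beta) / beta)

        alpha[idx] = alpha_new
        beta = beta_new
        active &= alpha <= prune_threshold
        m_full = m_new
        if rel < tol:
            converged = True
            break

    if not converged:
        logger.warning("ARD regression did not converge in %d iterations", max_iter)
    return SLRFit(
        weights=m_full,
        intercept=ym - xm @ m_full,
        alpha=np.where(active, alpha, np.inf),
        beta=beta,
        n_iter=it,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Decoder sets
# ---------------------------------------------------------------------------


@dataclass
class Decoder:
    """One feature unit's decoder: selected voxels, weights, intercept."""

    voxel_idx: np.ndarray
    weights: np.ndarray
    intercept: float
    converged: bool = True


@dataclass
class DecoderSet:
    """Per (ROI, layer, unit) decoders with the recorded normalization.

    ``roi_stats[roi] = (kept_voxel_idx, mean, sd)`` are training statistics
    of the non-degenerate voxels; ``feature_stats[layer] = (unit_idx, mean,
    sd)`` are training statistics of the selected feature units (shared
    across ROIs); ``models[(roi, layer)]`` is one :class:`Decoder` per
    selected unit.
    """

    roi_stats: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    feature_stats: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    models: dict[tuple[str, str], list[Decoder]] = field(default_factory=dict)

    @property
    def rois(self) -> list[str]:
        return list(self.roi_stats)

    @property
    def layers(self) -> list[str]:
        return list(self.feature_stats)

    def unit_indices(self, layer: str) -> np.ndarray:
        return self.feature_stats[layer][0]


def train_decoders(
    train_patterns: dict[str, np.ndarray],
    train_features: dict[str, np.ndarray],
    k_voxels: int = 500,
    k_features: int = 1000,
    unit_indices: dict[str, np.ndarray] | None = None,
    signed_selection: bool = False,
    **slr_kwargs,
) -> DecoderSet:
    """Fit one sparse decoder per selected feature unit per ROI x layer.

    ``train_patterns`` maps ROI name to its ``(n_stimuli, n_voxels)``
    training patterns, ``train_features`` maps layer label to the full
    ``(n_stimuli, n_units)`` training feature matrix.  If ``unit_indices``
    is not given, units are picked by cross-validated decodability computed
    on the pooled training patterns of all ROIs.

    Only training data enters this function: every recorded mean/SD, voxel
    selection and weight is a function of the training partition alone.
    """
    rois = list(train_patterns)
    layers = list(train_features)

    # normalize patterns per ROI, dropping zero-variance voxels
    roi_stats: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    normalized: dict[str, np.ndarray] = {}
    for roi in rois:
        X = np.asarray(train_patterns[roi], dtype=float)
        sd = X.std(0)
        kept = np.flatnonzero(sd > 0)
        mean = X[:, kept].mean(0)
        sd = X[:, kept].std(0)
        roi_stats[roi] = (kept, mean, sd)
        normalized[roi] = (X[:, kept] - mean) / sd

    if unit_indices is None:
        pooled = np.hstack([normalized[roi] for roi in rois])
        scores = []
        for layer in layers:
            Y = np.asarray(train_features[layer], dtype=float)
            s = crossval_unit_scores(pooled, Y)
            s[Y.std(0) == 0] = -np.inf  # degenerate units are never selected
            s[~np.isfinite(s)] = -np.inf
            sel_scores = np.where(np.isfinite(s), s, -1e30)
            scores.append(sel_scores)
        unit_indices = dict(zip(layers, select_feature_units(scores, k_features)))

    feature_stats: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    norm_features: dict[str, np.ndarray] = {}
    for layer in layers:
        idx = np.asarray(unit_indices[layer], dtype=int)
        Y = np.asarray(train_features[layer], dtype=float)[:, idx]
        sd = Y.std(0)
        keep = sd > 0
        if not np.all(keep):
            logger.info("dropping %d zero-variance units in %s", int((~keep).sum()), layer)
            idx = idx[keep]
            Y = Y[:, keep]
            sd = sd[keep]
        mean = Y.mean(0)
        feature_stats[layer] = (idx, mean, sd)
        norm_features[layer] = (Y - mean) / sd

    decoders = DecoderSet(roi_stats=roi_stats, feature_stats=feature_stats)
    for roi in rois:
        Xn = normalized[roi]
        # Xn is column-centered, so the full Gram can be reindexed per unit
        gram_full = Xn.T @ Xn
        for layer in layers:
            Yn = norm_features[layer]
            fits: list[Decoder] = []
            for u in range(Yn.shape[1]):
                y = Yn[:, u]
                vox = select_voxels(Xn, y, k=k_voxels, signed_selection=signed_selection)
                gram = gram_full[np.ix_(vox, vox)]
                fit = fit_sparse_regression(Xn[:, vox], y, gram=gram, **slr_kwargs)
                fits.append(
                    Decoder(voxel_idx=vox, weights=fit.weights,
                            intercept=fit.intercept, converged=fit.converged)
                )
            decoders.models[(roi, layer)] = fits
    return decoders


def predict_features(
    decoders: DecoderSet, test_patterns: dict[str, np.ndarray]
) -> dict[tuple[str, str], np.ndarray]:
    """Decode feature vectors from test patterns.

    Test patterns are normalized with the *recorded training* voxel
    means/SDs; predictions are denormalized by multiplying with the training
    feature SD only (the training mean is not added back), so the output
    lives in train-mean-centered feature space.
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    for roi, (kept, mean, sd) in decoders.roi_stats.items():
        if roi not in test_patterns:
            continue
        X = np.asarray(test_patterns[roi], dtype=float)
        if kept.size and X.shape[1] <= int(kept.max()):
            raise InvalidInputError(f"test pattern voxel count mismatch for ROI {roi}")
        Xn = (X[:, kept] - mean) / sd
        for layer, (unit_idx, fmean, fsd) in decoders.feature_stats.items():
            fits = decoders.models.get((roi, layer))
            if fits is None:
                continue
            W = np.zeros((len(fits), Xn.shape[1]))
            b = np.zeros(len(fits))
            for u, fit in enumerate(fits):
                W[u, fit.voxel_idx] = fit.weights
                b[u] = fit.intercept
            pred_norm = Xn @ W.T + b
            out[(roi, layer)] = pred_norm * fsd  # SD-only denormalization
    return out
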