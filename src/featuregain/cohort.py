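"""Synthetic multi-subject cohort generator with an injectable sharpening knob.

The generator emulates the study conditions of a blurred-image feature
decoding experiment: training runs of non-blurred images, test runs of
blurred-to-original 4-level sequences under a no-prior and a category-prior
condition, voxel responses that are noisy linear readouts of network-layer
features, four volumes per stimulus, per-run linear drift and baseline, and
probabilistic recognition/certainty reports.

Sharpening is modeled generatively as a convex interpolation in feature
space: the represented features of a trial are

    z* = (1 - alpha_layer) * z(stimulus) + alpha_layer * z(original)

so ``alpha = 0`` is a pure feedforward observation model (the null for the
downstream feature-gain analysis) and ``alpha = 1`` represents the original
image perfectly.  The profile actually used is recorded in the dataset as
ground truth for parameter-recovery tests.

Default sizes mirror the experimental design: 5 subjects, 1000 training
images in 20 runs of 50, and per condition 80 test sequences split across
two runs of 40, each sequence ordered 25% -> 12% -> 6% -> 0% blur.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._seeds import subseed, substream
from .errors import ConfigError, InvalidInputError
from .network import NetworkSpec, default_spec, extract_feature_matrices, layer_unit_counts
from .stimuli import DEFAULT_BLUR_FRACTIONS, generate_synthetic_images, make_blur_stack

__all__ = [
    "ROISpec",
    "COMPOSITE_ROIS",
    "default_rois",
    "SharpeningProfile",
    "BehaviorParams",
    "SubjectSpec",
    "CohortConfig",
    "EncodingModel",
    "RunData",
    "SubjectData",
    "CohortDataset",
    "build_encoding_model",
    "simulate_trial",
    "simulate_run",
    "chance_level",
    "recognition_fidelity",
    "simulate_behavior",
    "simulate_sequence_behavior",
    "plan_train_runs",
    "plan_test_sequences",
    "generate_cohort",
]

CONDITIONS = ("no-prior", "category-prior")
N_CATEGORIES = 5

#: Composite regions are unions of the voxel sets of their members.
COMPOSITE_ROIS: dict[str, tuple[str, ...]] = {
    "LVC": ("V1", "V2", "V3"),
    "HVC": ("LOC", "FFA", "PPA"),
    "VC": ("V1", "V2", "V3", "V4", "LOC", "FFA", "PPA"),
}


@dataclass(frozen=True)
class ROISpec:
    """An atomic region: name, voxel count and mixing weights over layers.

    ``layer_weights`` gives the probability that a voxel of this region reads
    its features from each network layer (shallow-weighted for early visual
    areas, deep-weighted for higher ones); they are non-negative and sum to 1.
    """

    name: str
    n_voxels: int
    layer_weights: tuple[float, ...]

    def __post_init__(self):
        w = np.asarray(self.layer_weights, dtype=float)
        if self.n_voxels < 1:
            raise ConfigError("ROI needs n_voxels >= 1", keys=(f"rois.{self.name}.n_voxels",))
        if w.ndim != 1 or w.size == 0 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ConfigError(
                "layer_weights must be non-negative and sum to 1",
                keys=(f"rois.{self.name}.layer_weights",),
            )
        object.__setattr__(self, "layer_weights", tuple(float(x) for x in w))


def _depth_weights(depth: float, n_layers: int, width: float = 0.25) -> tuple[float, ...]:
    """Bump of layer weights centered at relative depth ``depth`` in [0, 1]."""
    pos = np.linspace(0.0, 1.0, n_layers) if n_layers > 1 else np.array([0.5])
    w = np.exp(-(((pos - depth) / width) ** 2))
    return tuple(w / w.sum())


def default_rois(n_layers: int, n_voxels: int = 200) -> tuple[ROISpec, ...]:
    """The seven atomic visual regions with a shallow-to-deep readout ramp."""
    names = ("V1", "V2", "V3", "V4", "LOC", "FFA", "PPA")
    depths = np.linspace(0.0, 1.0, len(names))
    return tuple(
        ROISpec(name, n_voxels, _depth_weights(d, n_layers)) for name, d in zip(names, depths)
    )


@dataclass(frozen=True)
class SharpeningProfile:
    """Per-layer convex weights pulling represented features toward the original.

    ``no_prior`` and ``category_prior`` each hold one alpha in [0, 1] per
    layer.  This is the generative counterpart of the sharpening the analysis
    is designed to detect; it is ground truth for recovery tests, not a claim
    about any empirical magnitude.
    """

    no_prior: tuple[float, ...]
    category_prior: tuple[float, ...]

    def __post_init__(self):
        for attr in ("no_prior", "category_prior"):
            a = np.asarray(getattr(self, attr), dtype=float)
            if a.ndim != 1 or np.any(a < 0) or np.any(a > 1):
                raise ConfigError("alpha values must lie in [0, 1]", keys=(f"sharpening.{attr}",))
            object.__setattr__(self, attr, tuple(float(x) for x in a))
        if len(self.no_prior) != len(self.category_prior):
            raise ConfigError("condition profiles must cover the same layers",
                              keys=("sharpening",))

    @property
    def n_layers(self) -> int:
        return len(self.no_prior)

    def alpha(self, condition: str) -> np.ndarray:
        if condition == "no-prior":
            return np.asarray(self.no_prior)
        if condition == "category-prior":
            return np.asarray(self.category_prior)
        raise InvalidInputError(f"unknown condition {condition!r}")

    @classmethod
    def uniform(cls, alpha: float, n_layers: int, prior_boost: float = 0.0) -> "SharpeningProfile":
        base = (float(alpha),) * n_layers
        boosted = tuple(min(1.0, alpha + prior_boost) for _ in range(n_layers))
        return cls(no_prior=base, category_prior=boosted)

    @classmethod
    def depth_ramp(cls, low: float, high: float, n_layers: int,
                   prior_boost: float = 0.0) -> "SharpeningProfile":
        """Alphas increasing linearly from shallow to deep layers."""
        ramp = np.linspace(low, high, n_layers)
        return cls(
            no_prior=tuple(ramp),
            category_prior=tuple(np.minimum(1.0, ramp + prior_boost)),
        )


@dataclass(frozen=True)
class BehaviorParams:
    """Logistic coupling of trial fidelity to recognition/certainty reports."""

    slope: float = 8.0
    mid: float = 0.45
    cert_slope: float = 8.0
    cert_mid: float = 0.6
    p_missing: float = 0.05
    chance_no_prior: float = 0.02


@dataclass(frozen=True)
class SubjectSpec:
    subject_id: str
    seed: int
    noise_sd: float = 1.0
    drift_slope_range: tuple[float, float] = (-0.02, 0.02)
    behavior: BehaviorParams = field(default_factory=BehaviorParams)

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0", keys=("noise_sd",))


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of one synthetic cohort.

    Defaults are the full experimental design; tests and examples pass
    smaller numbers explicitly.
    """

    n_subjects: int = 5
    image_side: int = 32
    n_train_images: int = 1000
    train_run_size: int = 50
    n_test_sequences: int = 80  # per condition
    test_runs_per_condition: int = 2
    blur_fractions: tuple[float, ...] = DEFAULT_BLUR_FRACTIONS
    network: NetworkSpec = field(default_factory=default_spec)
    rois: tuple[ROISpec, ...] = ()
    sharpening: SharpeningProfile | None = None
    noise_sd: float = 1.0
    volumes_per_trial: int = 4
    shift_volumes: int = 1
    drift_slope_range: tuple[float, float] = (-0.02, 0.02)
    baseline_sd: float = 0.3
    encoding_sparsity: float = 0.05
    behavior: BehaviorParams = field(default_factory=BehaviorParams)

    def __post_init__(self):
        n_layers = len(self.network.layers)
        if not self.rois:
            object.__setattr__(self, "rois", default_rois(n_layers))
        if self.sharpening is None:
            # deep layers sharper, category prior adds a constant increment:
            # a qualitative imitation of the hierarchy/prior effects, exposed
            # in config rather than claimed as empirical truth
            object.__setattr__(
                self, "sharpening", SharpeningProfile.depth_ramp(0.1, 0.5, n_layers, 0.15)
            )

    def validate(self) -> None:
        bad: list[str] = []
        if self.n_subjects < 1:
            bad.append("n_subjects")
        if self.n_train_images < 1 or self.n_train_images % self.train_run_size != 0:
            bad.append("n_train_images/train_run_size")
        if self.n_test_sequences < 1 or self.n_test_sequences % self.test_runs_per_condition != 0:
            bad.append("n_test_sequences/test_runs_per_condition")
        fr = self.blur_fractions
        if (not fr or fr[-1] != 0.0 or any(nxt >= prev for nxt, prev in zip(fr[1:], fr[:-1]))
                or any(not 0.0 <= f < 1.0 for f in fr)):
            bad.append("blur_fractions")
        if self.sharpening.n_layers != len(self.network.layers):
            bad.append("sharpening")
        n_layers = len(self.network.layers)
        for roi in self.rois:
            if len(roi.layer_weights) != n_layers:
                bad.append(f"rois.{roi.name}.layer_weights")
        if self.noise_sd <= 0:
            bad.append("noise_sd")
        if self.volumes_per_trial < 1:
            bad.append("volumes_per_trial")
        if self.shift_volumes < 0:
            bad.append("shift_volumes")
        if not 0.0 < self.encoding_sparsity <= 1.0:
            bad.append("encoding_sparsity")
        if bad:
            raise ConfigError("invalid cohort configuration", keys=tuple(bad))

    @property
    def n_train_runs(self) -> int:
        return self.n_train_images // self.train_run_size

    @property
    def sequences_per_run(self) -> int:
        return self.n_test_sequences // self.test_runs_per_condition


# ---------------------------------------------------------------------------
# Encoding model
# ---------------------------------------------------------------------------


@dataclass
class EncodingModel:
    """Sparse random linear readout from layer features to voxels.

    Each voxel is assigned one layer (sampled from the region's
    ``layer_weights``) and reads a sparse random linear combination of that
    layer's standardized features; every voxel has at least one nonzero
    weight.  ``weights[l]`` is dense ``(n_voxels_of_layer_l, dim_l)`` and
    ``voxel_idx[l]`` maps its rows back to voxel positions.
    """

    n_voxels: int
    layer_labels: tuple[str, ...]
    layer_assignment: np.ndarray  # (n_voxels,) layer index per voxel
    weights: dict[int, np.ndarray]
    voxel_idx: dict[int, np.ndarray]

    def signal_matrix(self, z_std: dict[str, np.ndarray]) -> np.ndarray:
        """Noise-free voxel signals for standardized features ``{label: (n, dim)}``."""
        n = next(iter(z_std.values())).shape[0]
        out = np.zeros((n, self.n_voxels))
        for l, W in self.weights.items():
            out[:, self.voxel_idx[l]] = z_std[self.layer_labels[l]] @ W.T
        return out


def build_encoding_model(
    roi: ROISpec,
    layer_dims: Sequence[int],
    seed: int,
    sparsity: float = 0.05,
    layer_labels: Sequence[str] | None = None,
) -> EncodingModel:
    """Draw the voxel weight map of one region (deterministic given ``seed``)."""
    if any(d < 1 for d in layer_dims):
        raise InvalidInputError("layer dims must be positive")
    if not 0.0 < sparsity <= 1.0:
        raise InvalidInputError("sparsity must be in (0, 1]")
    n_layers = len(layer_dims)
    labels = tuple(layer_labels) if layer_labels else tuple(f"DNN{i+1}" for i in range(n_layers))
    rng = np.random.default_rng(seed)
    assignment = rng.choice(n_layers, size=roi.n_voxels, p=np.asarray(roi.layer_weights))
    weights: dict[int, np.ndarray] = {}
    voxel_idx: dict[int, np.ndarray] = {}
    for l in range(n_layers):
        vox = np.flatnonzero(assignment == l)
        if vox.size == 0:
            continue
        dim = int(layer_dims[l])
        mask = rng.random((vox.size, dim)) < sparsity
        empty = ~mask.any(axis=1)
        if np.any(empty):
            # guarantee >= 1 nonzero weight per voxel
            cols = rng.integers(0, dim, size=int(empty.sum()))
            mask[np.flatnonzero(empty), cols] = True
        W = rng.standard_normal((vox.size, dim)) * mask
        nnz = mask.sum(axis=1)
        W /= np.sqrt(nnz)[:, None]
        weights[l] = W
        voxel_idx[l] = vox
    return EncodingModel(
        n_voxels=roi.n_voxels,
        layer_labels=labels,
        layer_assignment=assignment,
        weights=weights,
        voxel_idx=voxel_idx,
    )


@dataclass
class Standardizer:
    """Per-layer per-unit mean/SD of the training features (SD floored)."""

    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]

    @classmethod
    def fit(cls, feature_mats: dict[str, np.ndarray]) -> "Standardizer":
        mean = {k: m.mean(axis=0) for k, m in feature_mats.items()}
        sd = {k: np.maximum(m.std(axis=0), 1e-8) for k, m in feature_mats.items()}
        return cls(mean=mean, sd=sd)

    def apply(self, feature_mats: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        return {k: (m - self.mean[k]) / self.sd[k] for k, m in feature_mats.items()}


def simulate_trial(
    model: EncodingModel,
    stim_features: dict[str, np.ndarray],
    orig_features: dict[str, np.ndarray],
    alphas: Sequence[float],
    noise_sd: float,
    rng: np.random.Generator,
    n_volumes: int = 4,
    standardizer: Standardizer | None = None,
) -> np.ndarray:
    """Simulate the ``n_volumes`` voxel vectors of one stimulus block.

    Represented features per layer are the convex interpolation
    ``(1 - alpha) * z(stimulus) + alpha * z(original)``; each volume is the
    noise-free signal plus independent Gaussian noise of SD ``noise_sd``.
    ``stim_features``/``orig_features`` map layer label to a 1-D vector.
    """
    if set(stim_features) != set(orig_features):
        raise InvalidInputError("stimulus and original features must share the network spec")
    alphas = np.asarray(alphas, dtype=float)
    if alphas.size != len(model.layer_labels):
        raise InvalidInputError("one alpha per layer required")
    z_star: dict[str, np.ndarray] = {}
    for i, label in enumerate(model.layer_labels):
        zs = np.atleast_2d(stim_features[label])
        zo = np.atleast_2d(orig_features[label])
        if zs.shape != zo.shape:
            raise InvalidInputError("stimulus and original features must share shapes")
        z_star[label] = (1.0 - alphas[i]) * zs + alphas[i] * zo
    if standardizer is not None:
        z_star = standardizer.apply(z_star)
    signal = model.signal_matrix(z_star)[0]
    volumes = np.tile(signal, (n_volumes, 1))
    if noise_sd > 0:
        volumes += rng.standard_normal((n_volumes, model.n_voxels)) * noise_sd
    return volumes


@dataclass
class RunData:
    """One run's time series plus the bookkeeping preprocessing needs.

    ``boundaries`` are trial windows in post-shift coordinates: after the
    preprocessing step drops the first ``shift_volumes`` rows, trial ``i``
    occupies rows ``boundaries[i][0]:boundaries[i][1]``.
    """

    series: np.ndarray  # (T, n_voxels)
    boundaries: tuple[tuple[int, int], ...]
    shift_volumes: int = 1


def simulate_run(
    trial_blocks: Sequence[np.ndarray],
    drift_slope: float = 0.0,
    baseline: np.ndarray | float = 0.0,
    shift_volumes: int = 1,
) -> RunData:
    """Concatenate trial volumes into a run with baseline and linear drift.

    The hemodynamic delay is represented as ``shift_volumes`` leading
    baseline-only volumes, so that shifting by the same amount in
    preprocessing re-aligns trials with their volumes.
    """
    if len(trial_blocks) < 1:
        raise InvalidInputError("a run needs at least one trial")
    n_vox = trial_blocks[0].shape[1]
    lead = np.zeros((shift_volumes, n_vox))
    series = np.vstack([lead] + [np.asarray(b, dtype=float) for b in trial_blocks])
    series = series + np.asarray(baseline, dtype=float)
    series = series + drift_slope * np.arange(series.shape[0], dtype=float)[:, None]
    bounds = []
    start = 0
    for b in trial_blocks:
        bounds.append((start, start + b.shape[0]))
        start += b.shape[0]
    return RunData(series=series, boundaries=tuple(bounds), shift_volumes=shift_volumes)


# ---------------------------------------------------------------------------
# Behavior
# ---------------------------------------------------------------------------


def chance_level(condition: str, params: BehaviorParams | None = None) -> float:
    """Guessing accuracy: 1/5 under the category prior, near zero without."""
    params = params or BehaviorParams()
    if condition == "category-prior":
        return 1.0 / N_CATEGORIES
    if condition == "no-prior":
        return params.chance_no_prior
    raise InvalidInputError(f"unknown condition {condition!r}")


def recognition_fidelity(blur_fraction: float, mean_alpha: float,
                         max_fraction: float = 0.25) -> float:
    """Monotone map from (blur level, ground-truth sharpening) to [0, 1].

    Behavior only needs the right statistical coupling for the grouping
    analyses, so fidelity is computed from the generative state, not from
    image content: full fidelity at 0% blur, degraded in proportion to blur,
    partially restored by sharpening.
    """
    if not 0.0 <= blur_fraction:
        raise InvalidInputError("blur_fraction must be >= 0")
    d = min(1.0, blur_fraction / max_fraction) if max_fraction > 0 else 0.0
    return float(np.clip(1.0 - d * (1.0 - mean_alpha), 0.0, 1.0))


def simulate_behavior(
    fidelity: float,
    condition: str,
    params: BehaviorParams,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """One trial's (correct, certain) reports.

    ``P(correct) = chance + (1 - chance) * logistic(slope * (fidelity - mid))``
    and analogously for certainty with its own slope/midpoint.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise InvalidInputError("fidelity must lie in [0, 1]")
    chance = chance_level(condition, params)
    p_correct = chance + (1.0 - chance) * expit(params.slope * (fidelity - params.mid))
    p_certain = expit(params.cert_slope * (fidelity - params.cert_mid))
    return int(rng.random() < p_correct), int(rng.random() < p_certain)


def simulate_sequence_behavior(
    fidelities: Sequence[float],
    condition: str,
    params: BehaviorParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Behavioral reports for one blurred-to-original sequence.

    Button (certainty) responses go missing with probability ``p_missing``;
    a missing response copies the previous response in the sequence, except
    that a missing first response is set to uncertain and a missing last
    response (the original image) to certain.
    """
    n = len(fidelities)
    correct = np.zeros(n, dtype=int)
    certain = np.zeros(n, dtype=int)
    missing = rng.random(n) < params.p_missing
    for i, f in enumerate(fidelities):
        correct[i], certain[i] = simulate_behavior(float(f), condition, params, rng)
    for i in range(n):
        if missing[i]:
            if i == 0:
                certain[i] = 0
            elif i == n - 1:
                certain[i] = 1
            else:
                certain[i] = certain[i - 1]
    return correct, certain


# ---------------------------------------------------------------------------
# Design plans (cheap, no simulation)
# ---------------------------------------------------------------------------


def plan_train_runs(config: CohortConfig) -> list[list[int]]:
    """Partition of training image indices into runs (run-major order)."""
    config.validate()
    n, size = config.n_train_images, config.train_run_size
    return [list(range(r * size, (r + 1) * size)) for r in range(n // size)]


def plan_test_sequences(config: CohortConfig, master_seed: int = 0) -> pd.DataFrame:
    """Sequence table: one row per test sequence with condition/run/category.

    Sequence order within a run is shuffled deterministically from the master
    seed; categories cycle through the five motifs in the category-prior
    condition and are drawn at random in the no-prior condition.
    """
    config.validate()
    rng = substream(master_seed, "test-design")
    rows = []
    seq_id = 0
    for cond in CONDITIONS:
        order = rng.permutation(config.n_test_sequences)
        per_run = config.sequences_per_run
        for pos, k in enumerate(order):
            if cond == "category-prior":
                category = int(k) % N_CATEGORIES
            else:
                category = int(rng.integers(0, N_CATEGORIES))
            rows.append(
                {
                    "sequence_id": seq_id,
                    "condition": cond,
                    "run": pos // per_run,
                    "category": category,
                }
            )
            seq_id += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    spec: SubjectSpec
    train_runs: list[RunData]
    test_runs: list[RunData]  # ordered as in test_meta (condition-major, then run)
    behavior: pd.DataFrame  # trial, correct, certain


@dataclass
class CohortDataset:
    """Everything downstream stages need, plus the generative ground truth."""

    config: CohortConfig
    master_seed: int
    roi_voxels: dict[str, np.ndarray]  # atomic and composite -> voxel indices
    train_meta: pd.DataFrame
    test_meta: pd.DataFrame  # trial-level design shared across subjects
    subjects: list[SubjectData]
    train_features: dict[str, np.ndarray]
    test_stim_features: dict[str, np.ndarray]  # per trial
    test_orig_features: dict[str, np.ndarray]  # per trial (0% rendition)
    standardizer: Standardizer
    profile: SharpeningProfile

    @property
    def n_voxels(self) -> int:
        return sum(r.n_voxels for r in self.config.rois)

    @property
    def layer_labels(self) -> tuple[str, ...]:
        return self.config.network.labels

    def subject_test_meta(self, subject_index: int) -> pd.DataFrame:
        return self.test_meta.merge(self.subjects[subject_index].behavior, on="trial")


def _roi_voxel_map(rois: Sequence[ROISpec]) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    start = 0
    for roi in rois:
        out[roi.name] = np.arange(start, start + roi.n_voxels)
        start += roi.n_voxels
    atomic = set(out)
    for comp, members in COMPOSITE_ROIS.items():
        present = [m for m in members if m in atomic]
        if len(present) == len(members):
            out[comp] = np.concatenate([out[m] for m in members])
    return out


def generate_cohort(config: CohortConfig, master_seed: int) -> CohortDataset:
    """Generate the full synthetic cohort; bit-reproducible given the seed."""
    config.validate()
    n_layers = len(config.network.layers)
    labels = config.network.labels
    dims = layer_unit_counts(config.network)

    # --- stimuli -----------------------------------------------------------
    seq_table = plan_test_sequences(config, master_seed)
    n_test = len(seq_table)
    n_train = config.n_train_images
    categories = np.empty(n_train + n_test, dtype=int)
    img_rng = substream(master_seed, "image-categories")
    categories[:n_train] = img_rng.integers(0, N_CATEGORIES, size=n_train)
    categories[n_train:] = seq_table["category"].to_numpy()
    images = generate_synthetic_images(
        n_train + n_test, config.image_side, seed=subseed(master_seed, "images"),
        categories=categories,
    )
    train_images = images[:n_train]
    test_images = images[n_train:]

    # --- features ----------------------------------------------------------
    train_features = extract_feature_matrices(config.network, train_images)
    standardizer = Standardizer.fit(train_features)

    # per-sequence blur stacks; trial-level stimulus and original features
    fractions = config.blur_fractions
    n_levels = len(fractions)
    stacks = [make_blur_stack(img, fractions) for img in test_images]
    rendition_mats = extract_feature_matrices(
        config.network, [r for s in stacks for r in s.renditions]
    )

    # --- trial-level test design --------------------------------------------
    trial_rows = []
    trial = 0
    for _, seq in seq_table.iterrows():
        for fraction in fractions:
            trial_rows.append(
                {
                    "trial": trial,
                    "sequence_id": int(seq["sequence_id"]),
                    "image_id": f"test-{int(seq['sequence_id']):04d}",
                    "blur": float(fraction),
                    "condition": seq["condition"],
                    "run": int(seq["run"]),
                    "category": int(seq["category"]),
                }
            )
            trial += 1
    test_meta = pd.DataFrame(trial_rows)

    test_stim_features = {lab: rendition_mats[lab] for lab in labels}
    orig_rows = np.repeat(
        np.arange(n_test) * n_levels + (n_levels - 1), n_levels
    )
    test_orig_features = {lab: rendition_mats[lab][orig_rows] for lab in labels}

    train_meta = pd.DataFrame(
        {
            "stimulus_id": [f"train-{i:04d}" for i in range(n_train)],
            "run": np.repeat(np.arange(config.n_train_runs), config.train_run_size),
            "category": categories[:n_train],
        }
    )

    # --- subjects ----------------------------------------------------------
    train_std = standardizer.apply(train_features)
    stim_std = standardizer.apply(test_stim_features)
    orig_std = standardizer.apply(test_orig_features)

    subjects: list[SubjectData] = []
    for s in range(config.n_subjects):
        sid = f"S{s + 1}"
        spec = SubjectSpec(
            subject_id=sid,
            seed=subseed(master_seed, "subject", s),
            noise_sd=config.noise_sd,
            drift_slope_range=config.drift_slope_range,
            behavior=config.behavior,
        )
        models = [
            build_encoding_model(
                roi, dims, seed=subseed(master_seed, "encoding", s, roi.name),
                sparsity=config.encoding_sparsity, layer_labels=labels,
            )
            for roi in config.rois
        ]

        def full_signal(z_std: dict[str, np.ndarray]) -> np.ndarray:
            return np.hstack([m.signal_matrix(z_std) for m in models])

        noise_rng = substream(master_seed, "noise", s)
        run_rng = substream(master_seed, "run-params", s)
        n_vox_total = sum(r.n_voxels for r in config.rois)

        # training runs
        train_signal = full_signal(train_std)
        train_runs: list[RunData] = []
        for r in range(config.n_train_runs):
            rows = slice(r * config.train_run_size, (r + 1) * config.train_run_size)
            blocks = [
                sig[None, :]
                + noise_rng.standard_normal((config.volumes_per_trial, n_vox_total))
                * config.noise_sd
                for sig in train_signal[rows]
            ]
            slope = run_rng.uniform(*config.drift_slope_range)
            baseline = run_rng.normal(0.0, config.baseline_sd, size=n_vox_total)
            train_runs.append(
                simulate_run(blocks, slope, baseline, shift_volumes=config.shift_volumes)
            )

        # test runs: one run object per (condition, run), trials in design order
        test_runs: list[RunData] = []
        for cond in CONDITIONS:
            alphas = config.sharpening.alpha(cond)
            for run_no in range(config.test_runs_per_condition):
                idx = test_meta.index[
                    (test_meta["condition"] == cond) & (test_meta["run"] == run_no)
                ].to_numpy()
                z_star = {
                    lab: (1.0 - alphas[i]) * stim_std[lab][idx]
                    + alphas[i] * orig_std[lab][idx]
                    for i, lab in enumerate(labels)
                }
                signals = full_signal(z_star)
                blocks = [
                    sig[None, :]
                    + noise_rng.standard_normal((config.volumes_per_trial, n_vox_total))
                    * config.noise_sd
                    for sig in signals
                ]
                slope = run_rng.uniform(*config.drift_slope_range)
                baseline = run_rng.normal(0.0, config.baseline_sd, size=n_vox_total)
                test_runs.append(
                    simulate_run(blocks, slope, baseline, shift_volumes=config.shift_volumes)
                )

        # behavior, sequence by sequence
        beh_rng = substream(master_seed, "behavior", s)
        records = []
        for _, seq in seq_table.iterrows():
            cond = seq["condition"]
            mean_alpha = float(np.mean(config.sharpening.alpha(cond)))
            trials = test_meta[test_meta["sequence_id"] == seq["sequence_id"]]
            fids = [
                recognition_fidelity(b, mean_alpha, max_fraction=max(fractions))
                for b in trials["blur"]
            ]
            correct, certain = simulate_sequence_behavior(fids, cond, config.behavior, beh_rng)
            for t, c, ce in zip(trials["trial"], correct, certain):
                records.append({"trial": int(t), "correct": int(c), "certain": int(ce)})
        behavior = pd.DataFrame(records).sort_values("trial").reset_index(drop=True)

        subjects.append(
            SubjectData(spec=spec, train_runs=train_runs, test_runs=test_runs,
                        behavior=behavior)
        )

    return CohortDataset(
        config=config,
        master_seed=master_seed,
        roi_voxels=_roi_voxel_map(config.rois),
        train_meta=train_meta,
        test_meta=test_meta,
        subjects=subjects,
        train_features=train_features,
        test_stim_features=test_stim_features,
        test_orig_features=test_orig_features,
        standardizer=standardizer,
        profile=config.sharpening,
    )
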