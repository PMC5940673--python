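"""Hierarchical feedforward network surrogate and feature extraction.

The decoding analysis needs a fixed hierarchical feedforward map from images
to per-layer feature vectors, not a trained classifier.  Layers are
convolutions or fully connected maps with rectifier nonlinearities between
them (softmax nominally on the last layer); the stored features of layer *n*
are always the **pre-activation** values ``z_n = c_n(w_n, x_n) + b_n``, where
``x_n`` is the rectified output of layer *n - 1* and ``x_1`` is the input
image.  Weights are drawn once from a seeded standard normal scaled by
fan-in, so the map is deterministic given the spec; random hierarchical
weights preserve the local-to-global gradient across layers that the
analysis relies on, without any pretrained model.

Two packaged specs:

* :func:`reference_8layer_spec` - the classic 8-layer object-recognition
  architecture (5 conv + 3 fully connected, 227-pixel input) whose per-layer
  pre-activation unit counts are 290400, 186624, 64896, 64896, 43264, 4096,
  4096 and 1000.  It exists for the dimension calculator and for users who
  plug in real weights.
* :func:`default_spec` - a desk-scale network (32-pixel input, <= 2000 units
  per layer) used throughout the synthetic analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .errors import InvalidInputError, SpecError

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "FeatureTensor",
    "FeatureExtractor",
    "layer_unit_counts",
    "extract_features",
    "extract_feature_matrices",
    "select_feature_units",
    "reference_8layer_spec",
    "default_spec",
]


@dataclass(frozen=True)
class LayerSpec:
    """One layer: convolutional (kernel/stride/padding/filters) or fully connected.

    ``pool_size``/``pool_stride`` describe an optional max-pool applied to the
    rectified output when feeding the next layer (0 disables it); unit counts
    always refer to the pre-pool convolution output.
    """

    kind: str  # "conv" | "fc"
    n_filters: int = 0
    kernel: int = 0
    stride: int = 1
    padding: int = 0
    n_units: int = 0
    nonlinearity: str = "relu"  # "relu" | "softmax"
    pool_size: int = 0
    pool_stride: int = 2

    def __post_init__(self):
        if self.kind not in ("conv", "fc"):
            raise SpecError(f"unknown layer kind {self.kind!r}")
        if self.nonlinearity not in ("relu", "softmax"):
            raise SpecError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.kind == "conv":
            if self.kernel < 1 or self.n_filters < 1 or self.stride < 1 or self.padding < 0:
                raise SpecError("conv layer needs kernel>=1, n_filters>=1, stride>=1, padding>=0")
        else:
            if self.n_units < 1:
                raise SpecError("fc layer needs n_units >= 1")


@dataclass(frozen=True)
class NetworkSpec:
    input_side: int
    layers: tuple[LayerSpec, ...]
    weight_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "layers", tuple(self.layers))
        if self.input_side < 1:
            raise SpecError("input_side must be >= 1")
        if not self.layers:
            raise SpecError("network needs at least one layer")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"DNN{i + 1}" for i in range(len(self.layers)))


@dataclass
class FeatureTensor:
    """Per-layer pre-activation feature vectors of one image."""

    layers: tuple[np.ndarray, ...]
    labels: tuple[str, ...]
    selected: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.layers[self.labels.index(label)]


def layer_unit_counts(spec: NetworkSpec) -> list[int]:
    """Pre-activation unit count of every layer.

    Convolutional layers contribute ``out_side**2 * n_filters`` with
    ``out_side = (in_side + 2*pad - kernel) // stride + 1``; fully connected
    layers contribute ``n_units``.  Raises :class:`SpecError` on incompatible
    shapes (including a convolution following a fully connected layer).
    """
    counts: list[int] = []
    side = spec.input_side
    channels = 1
    spatial = True
    for i, layer in enumerate(spec.layers):
        name = f"layer {i + 1}"
        if layer.kind == "conv":
            if not spatial:
                raise SpecError(f"{name}: convolution cannot follow a fully connected layer")
            out_side = (side + 2 * layer.padding - layer.kernel) // layer.stride + 1
            if out_side < 1:
                raise SpecError(f"{name}: kernel {layer.kernel} too large for input side {side}")
            counts.append(out_side * out_side * layer.n_filters)
            channels = layer.n_filters
            side = out_side
            if layer.pool_size:
                pooled = (side - layer.pool_size) // layer.pool_stride + 1
                if pooled < 1:
                    raise SpecError(f"{name}: pool {layer.pool_size} too large for side {side}")
                side = pooled
        else:
            counts.append(layer.n_units)
            spatial = False
    return counts


def reference_8layer_spec(weight_seed: int = 0) -> NetworkSpec:
    """The 8-layer reference architecture (5 conv + 3 fc, 227-pixel input)."""
    return NetworkSpec(
        input_side=227,
        layers=(
            LayerSpec("conv", n_filters=96, kernel=11, stride=4, padding=0,
                      pool_size=3, pool_stride=2),
            LayerSpec("conv", n_filters=256, kernel=5, stride=1, padding=2,
                      pool_size=3, pool_stride=2),
            LayerSpec("conv", n_filters=384, kernel=3, stride=1, padding=1),
            LayerSpec("conv", n_filters=384, kernel=3, stride=1, padding=1),
            LayerSpec("conv", n_filters=256, kernel=3, stride=1, padding=1,
                      pool_size=3, pool_stride=2),
            LayerSpec("fc", n_units=4096),
            LayerSpec("fc", n_units=4096),
            LayerSpec("fc", n_units=1000, nonlinearity="softmax"),
        ),
        weight_seed=weight_seed,
    )


def default_spec(n_layers: int = 5, input_side: int = 32, weight_seed: int = 0) -> NetworkSpec:
    """Desk-scale surrogate network (3 or 5 layers, <= 2000 units per layer)."""
    if n_layers == 5:
        layers = (
            LayerSpec("conv", n_filters=10, kernel=7, stride=3, padding=2),
            LayerSpec("conv", n_filters=16, kernel=3, stride=1, padding=1),
            LayerSpec("conv", n_filters=20, kernel=3, stride=2, padding=1),
            LayerSpec("fc", n_units=256),
            LayerSpec("fc", n_units=100, nonlinearity="softmax"),
        )
    elif n_layers == 3:
        layers = (
            LayerSpec("conv", n_filters=10, kernel=7, stride=3, padding=2),
            LayerSpec("conv", n_filters=16, kernel=3, stride=2, padding=1),
            LayerSpec("fc", n_units=120, nonlinearity="softmax"),
        )
    else:
        raise SpecError("default_spec provides 3- or 5-layer variants")
    if input_side != 32:
        # same layout, recomputed geometry; caller is responsible for validity
        pass
    return NetworkSpec(input_side=input_side, layers=layers, weight_seed=weight_seed)


class FeatureExtractor:
    """Materialized weights for a :class:`NetworkSpec`.

    ``weights`` may be supplied explicitly as a list of ``(W, b)`` pairs (used
    by tests to plant exact maps); otherwise they are drawn from
    ``default_rng(spec.weight_seed)`` layer by layer, N(0, 1) scaled by
    ``1/sqrt(fan_in)``, biases N(0, 0.1).
    """

    def __init__(self, spec: NetworkSpec, weights: list[tuple[np.ndarray, np.ndarray]] | None = None):
        self.spec = spec
        self.unit_counts = layer_unit_counts(spec)
        if weights is not None:
            self.weights = weights
            return
        rng = np.random.default_rng(spec.weight_seed)
        self.weights = []
        side = spec.input_side
        channels = 1
        flat_dim = side * side * channels
        for layer in spec.layers:
            if layer.kind == "conv":
                fan_in = channels * layer.kernel * layer.kernel
                W = rng.standard_normal((layer.n_filters, channels, layer.kernel, layer.kernel))
                W /= np.sqrt(fan_in)
                b = 0.1 * rng.standard_normal(layer.n_filters)
                out_side = (side + 2 * layer.padding - layer.kernel) // layer.stride + 1
                channels = layer.n_filters
                side = out_side
                if layer.pool_size:
                    side = (side - layer.pool_size) // layer.pool_stride + 1
                flat_dim = channels * side * side
            else:
                W = rng.standard_normal((layer.n_units, flat_dim)) / np.sqrt(flat_dim)
                b = 0.1 * rng.standard_normal(layer.n_units)
                flat_dim = layer.n_units
            self.weights.append((W, b))

    def __call__(self, image: np.ndarray) -> FeatureTensor:
        img = np.asarray(image, dtype=float)
        if img.shape != (self.spec.input_side, self.spec.input_side):
            raise InvalidInputError(
                f"image side {img.shape} does not match spec input side {self.spec.input_side}"
            )
        x = img[None, :, :]  # (channels, h, w)
        flat: np.ndarray | None = None
        stored: list[np.ndarray] = []
        n_layers = len(self.spec.layers)
        for i, layer in enumerate(self.spec.layers):
            W, b = self.weights[i]
            if layer.kind == "conv":
                if flat is not None:
                    raise SpecError("convolution cannot follow a fully connected layer")
                z = _conv2d(x, W, b, layer.stride, layer.padding)
                stored.append(z.ravel().copy())
                if i < n_layers - 1:
                    x = np.maximum(z, 0.0)
                    if layer.pool_size:
                        x = _maxpool(x, layer.pool_size, layer.pool_stride)
            else:
                if flat is None:
                    flat = x.ravel()
                z = W @ flat + b
                stored.append(z.copy())
                if i < n_layers - 1:
                    # the softmax of a final layer is never applied to stored
                    # features; intermediate layers use the rectifier
                    flat = np.maximum(z, 0.0)
        return FeatureTensor(layers=tuple(stored), labels=self.spec.labels)


def _conv2d(x: np.ndarray, W: np.ndarray, b: np.ndarray, stride: int, padding: int) -> np.ndarray:
    """Valid cross-correlation with zero padding via im2col."""
    c, h, w = x.shape
    k = W.shape[2]
    if padding:
        x = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    windows = windows[:, ::stride, ::stride, :, :]  # (c, H, W, k, k)
    z = np.tensordot(W, windows, axes=([1, 2, 3], [0, 3, 4]))  # (f, H, W)
    return z + b[:, None, None]


def _maxpool(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    windows = np.lib.stride_tricks.sliding_window_view(x, (size, size), axis=(1, 2))
    return windows[:, ::stride, ::stride, :, :].max(axis=(-2, -1))


@lru_cache(maxsize=8)
def _cached_extractor(spec: NetworkSpec) -> FeatureExtractor:
    return FeatureExtractor(spec)


def extract_features(spec: NetworkSpec, image: np.ndarray) -> FeatureTensor:
    """Pre-activation features of one image (deterministic given the spec)."""
    return _cached_extractor(spec)(image)


def extract_feature_matrices(spec: NetworkSpec, images: Sequence[np.ndarray]) -> dict[str, np.ndarray]:
    """Stack per-layer features of many images into ``{label: (n, units)}``."""
    extractor = _cached_extractor(spec)
    mats: dict[str, list[np.ndarray]] = {label: [] for label in spec.labels}
    for img in images:
        tensor = extractor(img)
        for label, vec in zip(tensor.labels, tensor.layers):
            mats[label].append(vec)
    return {label: np.vstack(vs) for label, vs in mats.items()}


def select_feature_units(scores: Sequence[np.ndarray], k: int) -> list[np.ndarray]:
    """Top-``k`` unit indices per layer by decodability score.

    Descending score, ties broken by ascending index; a layer with at most
    ``k`` units keeps all its units (the last layer of the reference network
    has exactly 1000 units and is kept whole).
    """
    if k <= 0:
        raise InvalidInputError("k must be positive")
    selected: list[np.ndarray] = []
    for s in scores:
        s = np.asarray(s, dtype=float)
        if s.ndim != 1:
            raise InvalidInputError("scores must be 1-D per layer")
        if not np.all(np.isfinite(s)):
            raise InvalidInputError("scores must be finite")
        order = np.lexsort((np.arange(s.size), -s))
        selected.append(order[: min(k, s.size)])
    return selected
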