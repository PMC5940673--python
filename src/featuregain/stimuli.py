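"""Stimulus construction: square grayscale images and box-filter blur stacks.

Images are plain 2-D ``float64`` numpy arrays with luminance in [0, 1]
(row-major, 0-based coordinates).  Degradation is a square moving-average
("box") filter whose side is a stated fraction of the image side; a blur
stack holds the ordered renditions of one base image from the strongest blur
down to the untouched original, mirroring a blurred-to-original presentation
sequence.

Boundary handling for the filter is symmetric (mirror) padding with a
same-size output, so constant images are preserved and no dark frame is
introduced.  The kernel side is ``max(1, round(fraction * side))`` with
half-up rounding; even kernels anchor on the top-left of the (absent) center.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from .errors import InvalidInputError

__all__ = [
    "DEFAULT_BLUR_FRACTIONS",
    "BlurStack",
    "center_crop_square",
    "kernel_side",
    "box_blur",
    "make_blur_stack",
    "generate_synthetic_images",
    "write_png",
    "read_png",
    "save_blur_stacks",
]

#: Filter side as a fraction of the image side, strongest blur first;
#: 0.0 denotes the non-blurred original.
DEFAULT_BLUR_FRACTIONS: tuple[float, ...] = (0.25, 0.12, 0.06, 0.0)


def _as_image(image, *, square: bool = True) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise InvalidInputError("image must be a non-empty 2-D array")
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("image contains non-finite values")
    if square and arr.shape[0] != arr.shape[1]:
        raise InvalidInputError(f"image must be square, got shape {arr.shape}")
    return arr


def center_crop_square(image) -> np.ndarray:
    """Crop a rectangular luminance grid to the centered square.

    The output side equals ``min(height, width)``; when the margin parity
    differs the offset is floored, i.e. the crop sits one pixel closer to the
    top/left.
    """
    arr = _as_image(image, square=False)
    h, w = arr.shape
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return arr[r0 : r0 + side, c0 : c0 + side].copy()


def kernel_side(fraction: float, side: int) -> int:
    """Box-filter side in pixels for a blur ``fraction`` of the image side."""
    if not 0.0 <= fraction < 1.0:
        raise InvalidInputError(f"blur fraction must be in [0, 1), got {fraction}")
    return max(1, int(np.floor(fraction * side + 0.5)))


def box_blur(image, fraction: float) -> np.ndarray:
    """Moving average with a square uniform kernel, same-size output.

    Symmetric (mirror) padding; ``fraction == 0.0`` (or any fraction with a
    1-pixel kernel) returns the image unchanged.
    """
    arr = _as_image(image)
    side = arr.shape[0]
    k = kernel_side(fraction, side)
    if k == 1:
        return arr.copy()
    lo = k // 2
    hi = k - 1 - lo
    padded = np.pad(arr, ((lo, hi), (lo, hi)), mode="symmetric")
    # summed-area table; window for output (i, j) covers padded rows [i, i+k)
    sat = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1))
    sat[1:, 1:] = padded.cumsum(axis=0).cumsum(axis=1)
    n = side
    total = (
        sat[k : k + n, k : k + n]
        - sat[0:n, k : k + n]
        - sat[k : k + n, 0:n]
        + sat[0:n, 0:n]
    )
    return total / float(k * k)


@dataclass(frozen=True)
class BlurStack:
    """One base image with its ordered blurred renditions.

    ``fractions`` are strictly decreasing and end at 0.0; the last rendition
    is pixel-identical to ``base``.
    """

    base: np.ndarray
    fractions: tuple[float, ...]
    renditions: tuple[np.ndarray, ...]

    def __iter__(self):
        return iter(zip(self.fractions, self.renditions))


def make_blur_stack(base, fractions: Sequence[float] = DEFAULT_BLUR_FRACTIONS) -> BlurStack:
    """Build the blurred-to-original rendition stack of one base image."""
    arr = _as_image(base)
    fr = tuple(float(f) for f in fractions)
    if len(fr) == 0:
        raise InvalidInputError("fractions must be non-empty")
    if any(not 0.0 <= f < 1.0 for f in fr):
        raise InvalidInputError("blur fractions must lie in [0, 1)")
    if any(nxt >= prev for nxt, prev in zip(fr[1:], fr[:-1])):
        raise InvalidInputError(f"fractions must be strictly decreasing, got {fr}")
    if fr[-1] != 0.0:
        raise InvalidInputError("the last fraction must be 0.0 (the original image)")
    renditions = tuple(box_blur(arr, f) if f > 0.0 else arr.copy() for f in fr)
    return BlurStack(base=arr, fractions=fr, renditions=renditions)


# ---------------------------------------------------------------------------
# Synthetic stimulus images
# ---------------------------------------------------------------------------

N_MOTIFS = 5

# Category motifs: relative (dy, dx, angle) of oriented ridges composing a
# centered object.  Five motifs stand in for the five prior-condition object
# categories; per-image jitter keeps every image distinct.
_MOTIF_LAYOUTS: dict[int, tuple[tuple[float, float, float], ...]] = {
    0: ((-0.18, 0.0, 0.0), (0.18, 0.0, 0.0), (0.0, 0.0, np.pi / 2)),
    1: ((-0.10, -0.10, np.pi / 4), (0.10, 0.10, np.pi / 4), (0.0, 0.0, -np.pi / 4)),
    2: ((0.0, -0.18, np.pi / 2), (0.0, 0.18, np.pi / 2), (-0.15, 0.0, 0.0)),
    3: ((0.0, 0.0, 0.0), (0.0, 0.0, np.pi / 2), (0.16, 0.16, np.pi / 4)),
    4: ((-0.15, -0.15, np.pi / 3), (-0.15, 0.15, -np.pi / 3), (0.18, 0.0, 0.0)),
}


def _oriented_ridge(side: int, cy: float, cx: float, angle: float,
                    s_long: float, s_short: float) -> np.ndarray:
    ys, xs = np.mgrid[0:side, 0:side].astype(float)
    y = ys - cy
    x = xs - cx
    u = np.cos(angle) * x + np.sin(angle) * y
    v = -np.sin(angle) * x + np.cos(angle) * y
    return np.exp(-0.5 * ((u / s_long) ** 2 + (v / s_short) ** 2))


def generate_synthetic_images(
    n: int,
    side: int,
    seed: int,
    categories: Sequence[int] | None = None,
) -> list[np.ndarray]:
    """Deterministically generate ``n`` object-on-texture stimulus images.

    Each image places a few overlapping oriented ridges (a category motif
    with per-image jitter) on a textured background, plus fine-grained
    texture, so box blurring destroys local detail while global shape
    survives.  Values are clipped to [0, 1].

    ``categories`` optionally fixes the motif (0..4) per image; by default
    motifs are drawn at random.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if side < 16:
        raise InvalidInputError("side must be >= 16")
    rng = np.random.default_rng(seed)
    if categories is None:
        cats = rng.integers(0, N_MOTIFS, size=n)
    else:
        cats = np.asarray(list(categories), dtype=int)
        if cats.shape != (n,) or cats.min() < 0 or cats.max() >= N_MOTIFS:
            raise InvalidInputError(f"categories must be {n} integers in [0, {N_MOTIFS})")

    images: list[np.ndarray] = []
    center = (side - 1) / 2.0
    for i in range(n):
        background = box_blur(rng.standard_normal((side, side)), 0.12)
        bg_sd = background.std()
        background = 0.5 + 0.08 * (background - background.mean()) / (bg_sd + 1e-12)

        obj = np.zeros((side, side))
        layout = _MOTIF_LAYOUTS[int(cats[i])]
        for j, (dy, dx, angle) in enumerate(layout):
            cy = center + (dy + rng.normal(0.0, 0.03)) * side
            cx = center + (dx + rng.normal(0.0, 0.03)) * side
            ang = angle + rng.normal(0.0, 0.15)
            s_long = 0.14 * side * (1.0 + rng.normal(0.0, 0.10))
            s_short = 0.035 * side * (1.0 + rng.normal(0.0, 0.10))
            amp = 0.45 if j % 2 == 0 else -0.35
            obj += amp * _oriented_ridge(side, cy, cx, ang, abs(s_long), abs(s_short))

        texture = 0.05 * rng.standard_normal((side, side))
        images.append(np.clip(background + obj + texture, 0.0, 1.0))
    return images


# ---------------------------------------------------------------------------
# PNG / CSV interfaces
# ---------------------------------------------------------------------------

def write_png(path, image) -> None:
    """Write an image as 8-bit grayscale PNG."""
    arr = _as_image(image, square=False)
    data = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    PILImage.fromarray(data, mode="L").save(str(path))


def read_png(path) -> np.ndarray:
    """Read an 8-bit grayscale PNG back into a [0, 1] float image."""
    with PILImage.open(str(path)) as img:
        arr = np.asarray(img.convert("L"), dtype=float)
    return arr / 255.0


def save_blur_stacks(stacks: dict[str, BlurStack], directory) -> pd.DataFrame:
    """Write each rendition as PNG and return the manifest (also saved as CSV).

    Manifest columns: ``stack_id, fraction, file``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for stack_id, stack in stacks.items():
        for fraction, image in stack:
            fname = f"{stack_id}_blur{int(round(fraction * 100)):03d}.png"
            write_png(directory / fname, image)
            rows.append({"stack_id": stack_id, "fraction": fraction, "file": fname})
    manifest = pd.DataFrame(rows, columns=["stack_id", "fraction", "file"])
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
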