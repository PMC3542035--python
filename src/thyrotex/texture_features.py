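"""Three ROI texture features for B-mode thyroid ultrasound.

The feature triple computed from a region of interest (ROI) image ``Ls``:

``w1``
    Smoothness ``1 - 1/(1 + sigma**2)`` where ``sigma`` is the population
    standard deviation of the gray levels normalized to ``[0, 1]`` (divided
    by 255).  Zero for a constant region, approaching one as variance grows.
``w2``
    Minimum brightness after histogram denoising: the lowest gray level
    whose pixel count strictly exceeds 20 % of the modal count.
``w3``
    Percentage of final 8x8 blocks produced by a quadtree (square-tree)
    decomposition of the ROI with a 10 % brightness split threshold,
    relative to the padded square area.

All features operate on integer gray levels 0..255.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeatureVector",
    "QuadtreeResult",
    "compute_histogram",
    "feature_smoothness",
    "feature_min_brightness",
    "quadtree_decompose",
    "feature_quadtree8",
    "extract_features",
]

#: Fraction of the modal histogram count below which gray levels are
#: treated as noise when computing ``w2``.
NOISE_THRESHOLD = 0.2

#: Fraction of the full 8-bit range used as the quadtree split criterion.
SPLIT_FRACTION = 0.10


@dataclass(frozen=True)
class FeatureVector:
    """The texture feature triple ``(w1, w2, w3)``.

    Attributes
    ----------
    w1 : float
        Smoothness, dimensionless, in ``[0, 1)``; ``0`` iff the ROI is
        constant.
    w2 : int
        Denoised minimum brightness, a gray level in ``[0, 255]``.
    w3 : float
        Percentage of 8x8 quadtree blocks, in ``[0, 100]``.
    """

    w1: float
    w2: int
    w3: float

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3], dtype=float)


@dataclass(frozen=True)
class QuadtreeResult:
    """Blocks of a quadtree decomposition of an edge-padded square image.

    ``blocks`` is a tuple of ``(top, left, size)`` triples tiling the
    padded ``P x P`` square exactly; every size is a power of two and
    every position a multiple of its block size.
    """

    blocks: tuple[tuple[int, int, int], ...]
    padded_extent: tuple[int, int]

    def count_of_size(self, size: int) -> int:
        return sum(1 for _, _, s in self.blocks if s == size)


def _validate_roi(ls: np.ndarray) -> np.ndarray:
    arr = np.asarray(ls)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"ROI must be a non-empty 2-D array, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("ROI gray levels must lie in [0, 255]")
    return arr


def compute_histogram(ls: np.ndarray) -> np.ndarray:
    """256-bin gray-level histogram: ``counts[i]`` = pixels with level ``i``."""
    arr = _validate_roi(ls)
    return np.bincount(arr.astype(np.int64).ravel(), minlength=256)


def feature_smoothness(ls: np.ndarray) -> float:
    """Smoothness ``w1 = 1 - 1/(1 + sigma^2)`` on levels normalized by 255."""
    arr = _validate_roi(ls).astype(float) / 255.0
    sigma = arr.std()  # population std (ddof=0)
    return 1.0 - 1.0 / (1.0 + sigma * sigma)


def feature_min_brightness(ls: np.ndarray) -> int:
    """Lowest gray level whose count strictly exceeds 20 % of the modal count.

    The modal bin always survives its own threshold, so the result is
    well defined for every image.
    """
    counts = compute_histogram(ls)
    cutoff = NOISE_THRESHOLD * counts.max()
    surviving = np.nonzero(counts > cutoff)[0]
    return int(surviving[0])


def _pad_to_pow2_square(arr: np.ndarray) -> np.ndarray:
    rows, cols = arr.shape
    p = 1
    while p < max(rows, cols):
        p *= 2
    return np.pad(arr, ((0, p - rows), (0, p - cols)), mode="edge")


def quadtree_decompose(
    ls: np.ndarray, split_fraction: float = SPLIT_FRACTION
) -> QuadtreeResult:
    """Quadtree decomposition of the ROI after edge-padding to a power-of-two square.

    A block splits into four equal quadrants iff its gray-level range
    ``max - min`` strictly exceeds ``split_fraction * 255``; recursion
    stops at 1x1 blocks.
    """
    arr = _validate_roi(ls).astype(np.int16)
    padded = _pad_to_pow2_square(arr)
    p = padded.shape[0]
    threshold = split_fraction * 255.0

    blocks: list[tuple[int, int, int]] = []
    # Iterative stack; recursion depth is log2(P) but stack avoids limits.
    stack = [(0, 0, p)]
    while stack:
        top, left, size = stack.pop()
        block = padded[top : top + size, left : left + size]
        if size > 1 and float(block.max() - block.min()) > threshold:
            half = size // 2
            stack.append((top, left, half))
            stack.append((top, left + half, half))
            stack.append((top + half, left, half))
            stack.append((top + half, left + half, half))
        else:
            blocks.append((top, left, size))
    return QuadtreeResult(blocks=tuple(blocks), padded_extent=(p, p))


def feature_quadtree8(ls: np.ndarray) -> float:
    """Percentage of the padded area covered by final 8x8 quadtree blocks."""
    result = quadtree_decompose(ls)
    p = result.padded_extent[0]
    n8 = result.count_of_size(8)
    return 100.0 * (n8 * 64) / (p * p)


def extract_features(ls: np.ndarray) -> FeatureVector:
    """Compute the full ``(w1, w2, w3)`` triple for one ROI image."""
    return FeatureVector(
        w1=feature_smoothness(ls),
        w2=feature_min_brightness(ls),
        w3=feature_quadtree8(ls),
    )
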