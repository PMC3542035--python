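"""Image loading, median prefiltering, ROI extraction and ROI perturbation.

Coordinate convention: 0-based, half-open, row-major. An ROI spans rows
``[top, top + height)`` and columns ``[left, left + width)`` of its host
image.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "ROISpec",
    "AffinePerturbation",
    "MIN_ROI_SIZE",
    "load_image",
    "median_filter3",
    "extract_roi",
    "perturb_roi",
    "rotate_roi_content",
]

#: Minimum legal ROI side length in pixels.
MIN_ROI_SIZE = 10

#: Maximum |shift| in the perturbation protocol, pixels.
MAX_SHIFT = 20


class ROIBoundsError(ValueError):
    """Raised when an ROI (possibly perturbed) violates a placement constraint."""


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest inside a host image."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < MIN_ROI_SIZE or self.width < MIN_ROI_SIZE:
            raise ROIBoundsError(
                f"ROI cannot be smaller than {MIN_ROI_SIZE}x{MIN_ROI_SIZE} pixels "
                f"(got {self.height}x{self.width})"
            )

    @property
    def bottom(self) -> int:
        return self.top + self.height

    @property
    def right(self) -> int:
        return self.left + self.width

    def center(self) -> tuple[float, float]:
        """ROI center in pixel-center coordinates (row, col)."""
        return (self.top + (self.height - 1) / 2.0, self.left + (self.width - 1) / 2.0)

    def inside(self, image_extent: tuple[int, int]) -> bool:
        rows, cols = image_extent
        return self.top >= 0 and self.left >= 0 and self.bottom <= rows and self.right <= cols


@dataclass(frozen=True)
class AffinePerturbation:
    """ROI perturbation state: shift (dm, dn), resize (dM, dN), rotation phi.

    Shifts are bounded to +/-20 px and phi to [0, 180] degrees, matching
    the sensitivity protocol.  Rotation is applied by
    :func:`rotate_roi_content`, not by :func:`perturb_roi`.
    """

    dm: int = 0
    dn: int = 0
    dM: int = 0
    dN: int = 0
    phi: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.dm) > MAX_SHIFT or abs(self.dn) > MAX_SHIFT:
            raise ValueError(f"|shift| must be <= {MAX_SHIFT} px (got dm={self.dm}, dn={self.dn})")
        if not 0.0 <= self.phi <= 180.0:
            raise ValueError(f"phi must lie in [0, 180] degrees (got {self.phi})")

    def negated(self) -> "AffinePerturbation":
        return AffinePerturbation(-self.dm, -self.dn, -self.dM, -self.dN, self.phi)


def _to_uint8_grid(arr: np.ndarray) -> np.ndarray:
    return np.asarray(arr).astype(np.uint8)


def _luma(rgb: np.ndarray) -> np.ndarray:
    # ITU-R BT.601 luma weights; round half-up to integer gray levels.
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.floor(y + 0.5).astype(np.uint8)


def _load_dicom(path: Path) -> np.ndarray:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading DICOM files requires the optional 'pydicom' dependency "
            "(pip install thyrotex[dicom])"
        ) from exc
    ds = pydicom.dcmread(path)
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise ValueError(f"multi-frame DICOM is not supported: {path}")
    pixels = ds.pixel_array.astype(float)
    if pixels.ndim == 3:
        pixels = _luma(pixels).astype(float)
    center = getattr(ds, "WindowCenter", None)
    width = getattr(ds, "WindowWidth", None)
    if center is not None and width is not None:
        try:  # multi-valued windowing: use the first entry
            center = float(center[0]) if not np.isscalar(center) else float(center)
            width = float(width[0]) if not np.isscalar(width) else float(width)
        except TypeError:
            center, width = float(center), float(width)
        lo, hi = center - width / 2.0, center + width / 2.0
    else:
        lo, hi = float(pixels.min()), float(pixels.max())
    if hi <= lo:
        return np.zeros_like(pixels, dtype=np.uint8)
    scaled = np.clip((pixels - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    """Load a grayscale 8-bit image from a PNG or single-frame DICOM file.

    RGB(A) input is converted via BT.601 luma weighting; DICOM pixel data
    is rescaled to [0, 255] using its stored windowing when present, else
    min-max.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in {".dcm", ".dicom"}:
        return _load_dicom(path)
    if suffix == ".png":
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 2:
            if arr.dtype != np.uint8:
                arr = np.floor(arr.astype(float) / arr.max() * 255.0 + 0.5) if arr.max() > 255 else arr
            return _to_uint8_grid(arr)
        if arr.ndim == 3 and arr.shape[2] in (3, 4):
            return _luma(arr[..., :3].astype(float))
        raise ValueError(f"unsupported PNG layout {arr.shape} in {path}")
    raise ValueError(f"unsupported image format {suffix!r} for {path} (expected PNG or DICOM)")


def median_filter3(image: np.ndarray) -> np.ndarray:
    """3x3 median prefilter with edge replication; output extent equals input."""
    arr = np.asarray(image)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"image must be a non-empty 2-D array, got shape {arr.shape}")
    return ndimage.median_filter(arr, size=3, mode="nearest")


def extract_roi(image: np.ndarray, roi: ROISpec) -> np.ndarray:
    """Copy the ROI sub-image ``Ls`` out of the host image."""
    arr = np.asarray(image)
    if not roi.inside(arr.shape):
        raise ROIBoundsError(
            f"ROI rows [{roi.top}, {roi.bottom}) x cols [{roi.left}, {roi.right}) "
            f"is outside the {arr.shape[0]}x{arr.shape[1]} image"
        )
    return arr[roi.top : roi.bottom, roi.left : roi.right].copy()


def _symmetric_growth_shift(delta: int) -> int:
    # Growth/shrink is split about the ROI center; the odd extra pixel goes
    # to the bottom/right edge. int() truncates toward zero, which makes the
    # rule its own inverse under delta -> -delta.
    return int(delta / 2)


def perturb_roi(
    roi: ROISpec, pert: AffinePerturbation, image_extent: tuple[int, int]
) -> ROISpec:
    """Apply shift and symmetric resize to an ROI; rotation is handled separately.

    Size changes are distributed symmetrically about the ROI center with
    the odd pixel going to the bottom/right edge, so that perturbing by
    ``p`` then by ``-p`` returns the original ROI.
    """
    new_height = roi.height + pert.dM
    new_width = roi.width + pert.dN
    if new_height < MIN_ROI_SIZE or new_width < MIN_ROI_SIZE:
        raise ROIBoundsError(
            f"perturbed ROI {new_height}x{new_width} is below the minimum "
            f"{MIN_ROI_SIZE}x{MIN_ROI_SIZE} pixels"
        )
    new_top = roi.top + pert.dm - _symmetric_growth_shift(pert.dM)
    new_left = roi.left + pert.dn - _symmetric_growth_shift(pert.dN)
    new_roi = ROISpec(top=new_top, left=new_left, height=new_height, width=new_width)
    if not new_roi.inside(image_extent):
        raise ROIBoundsError(
            "moved or enlarged ROI may not exceed the limits of the image: "
            f"rows [{new_roi.top}, {new_roi.bottom}) x cols [{new_roi.left}, "
            f"{new_roi.right}) vs image {image_extent[0]}x{image_extent[1]}"
        )
    return new_roi


def rotate_roi_content(image: np.ndarray, roi: ROISpec, phi: float) -> np.ndarray:
    """Resample an ROI-sized window after rotating the sampling grid by ``phi``.

    The sampling grid is rotated about the ROI center and resampled from
    the *host* image with bilinear interpolation, so window corners are
    filled with real neighbouring pixels; results are rounded half-up to
    integers.  At 0, 90 (square ROI) and 180 degrees the rotated grid
    lands on pixel centers and the result is exact up to rounding.
    """
    arr = np.asarray(image)
    if not 0.0 <= phi <= 180.0:
        raise ValueError(f"phi must lie in [0, 180] degrees (got {phi})")
    if not roi.inside(arr.shape):
        raise ROIBoundsError("ROI is outside the host image")
    if phi == 0.0:
        return extract_roi(arr, roi)

    cr, cc = roi.center()
    theta = np.deg2rad(phi)
    cos_t, sin_t = np.cos(theta), np.sin(theta)

    rows = np.arange(roi.top, roi.bottom, dtype=float)
    cols = np.arange(roi.left, roi.right, dtype=float)
    grid_r, grid_c = np.meshgrid(rows, cols, indexing="ij")
    dr, dc = grid_r - cr, grid_c - cc
    src_r = cr + cos_t * dr - sin_t * dc
    src_c = cc + sin_t * dr + cos_t * dc

    eps = 1e-9
    if (
        src_r.min() < -eps
        or src_c.min() < -eps
        or src_r.max() > arr.shape[0] - 1 + eps
        or src_c.max() > arr.shape[1] - 1 + eps
    ):
        raise ROIBoundsError(
            f"rotated sampling window at phi={phi} deg exceeds the host image bounds"
        )
    sampled = ndimage.map_coordinates(
        arr.astype(float), [src_r, src_c], order=1, mode="nearest"
    )
    return np.clip(np.floor(sampled + 0.5), 0, 255).astype(np.uint8)
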