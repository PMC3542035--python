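"""Seeded synthetic B-mode-like speckle textures and multi-view cohorts.

Every subject carries four views (left/right lobe x transverse/longitudinal
section, tagged LO/RO/LD/RD).  The diseased class emulates hypoechogenic,
heterogeneous tissue: lower mean gray level and a higher density of
contrasting patches than the healthy class.

The speckle field is unit-mean multiplicative gamma noise with shape
``1 / speckle_scale**2``, a standard first-order approximation of fully
developed B-mode speckle, and is fully seedable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .roi_preprocess import ROISpec

__all__ = [
    "VIEW_TAGS",
    "HEALTHY",
    "PATIENT",
    "TextureParams",
    "SubjectRecord",
    "CohortConfig",
    "default_class_params",
    "generate_texture",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

VIEW_TAGS = ("LO", "RO", "LD", "RD")
HEALTHY = "healthy"
PATIENT = "patient"

#: Minimum clearance between ROI and image border, so every perturbation of
#: the robustness protocol (shifts to +/-20 px) stays inside the image.
ROI_MARGIN = 20


@dataclass(frozen=True)
class TextureParams:
    """Parameters of one synthetic texture class.

    ``blob_density`` is the expected count of contrasting patches per
    1000 px^2; ``blob_contrast`` the magnitude of their gray-level offset.
    """

    mean_level: float
    speckle_scale: float = 0.0
    blob_density: float = 0.0
    blob_contrast: float = 0.0
    smooth_sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_level <= 255.0:
            raise ValueError(f"mean_level must lie in [0, 255] (got {self.mean_level})")
        for name in ("speckle_scale", "blob_density", "blob_contrast", "smooth_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (got {getattr(self, name)})")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    label: str
    views: dict[str, tuple[np.ndarray, ROISpec]]

    def __post_init__(self) -> None:
        if set(self.views) != set(VIEW_TAGS):
            raise ValueError(f"subject must carry exactly the views {VIEW_TAGS}")


@dataclass(frozen=True)
class CohortConfig:
    n_healthy: int
    n_patient: int
    image_extent: tuple[int, int] = (128, 128)
    roi_extent: tuple[int, int] = (60, 60)
    seed: int = 0
    class_params: dict[str, TextureParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_healthy < 1 or self.n_patient < 1:
            raise ValueError("need at least one subject per class")
        rows, cols = self.image_extent
        rh, rw = self.roi_extent
        if rows - rh < 2 * ROI_MARGIN or cols - rw < 2 * ROI_MARGIN:
            raise ValueError(
                f"ROI {rh}x{rw} must fit inside the {rows}x{cols} image with "
                f">= {ROI_MARGIN} px margin on every side"
            )

    def params_for(self, label: str) -> TextureParams:
        if label in self.class_params:
            return self.class_params[label]
        return default_class_params(label)

    def centered_roi(self) -> ROISpec:
        rows, cols = self.image_extent
        rh, rw = self.roi_extent
        return ROISpec(top=(rows - rh) // 2, left=(cols - rw) // 2, height=rh, width=rw)


def default_class_params(label: str) -> TextureParams:
    """Documented default texture parameters per class.

    Magnitudes are calibrated so that the extracted features land in
    plausible tissue ranges (w1 of order 1e-3..1e-2, w2 tens of gray
    levels, w3 roughly 10-40 %), with the diseased class darker
    (hypoechogenic) and more heterogeneous than the healthy one.
    """
    if label == HEALTHY:
        return TextureParams(
            mean_level=120.0,
            speckle_scale=0.18,
            blob_density=0.3,
            blob_contrast=25.0,
            smooth_sigma=1.0,
        )
    if label == PATIENT:
        return TextureParams(
            mean_level=70.0,
            speckle_scale=0.32,
            blob_density=0.9,
            blob_contrast=40.0,
            smooth_sigma=1.0,
        )
    raise ValueError(f"unknown class label {label!r} (expected 'healthy' or 'patient')")


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def generate_texture(
    params: TextureParams, extent: tuple[int, int], seed: int
) -> np.ndarray:
    """Generate one synthetic speckle texture, deterministic in (params, extent, seed).

    Construction: constant base at ``mean_level``, multiplied by unit-mean
    gamma speckle with dispersion ``speckle_scale``, plus ``blob_density``
    randomly placed patches offset by +/-``blob_contrast``, Gaussian
    smoothing with ``smooth_sigma``, then clipping to [0, 255] and
    round-half-up quantization.
    """
    rows, cols = int(extent[0]), int(extent[1])
    if rows < 1 or cols < 1:
        raise ValueError(f"extent must be >= 1x1 (got {rows}x{cols})")
    rng = np.random.default_rng(seed)

    img = np.full((rows, cols), params.mean_level, dtype=float)
    if params.speckle_scale > 0:
        shape = 1.0 / (params.speckle_scale**2)
        img *= rng.gamma(shape, scale=1.0 / shape, size=(rows, cols))
    if params.blob_density > 0:
        n_blobs = int(round(params.blob_density * rows * cols / 1000.0))
        for _ in range(n_blobs):
            br = int(rng.integers(3, 9))
            bc = int(rng.integers(3, 9))
            r0 = int(rng.integers(0, max(rows - br, 1)))
            c0 = int(rng.integers(0, max(cols - bc, 1)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            img[r0 : r0 + br, c0 : c0 + bc] += sign * params.blob_contrast
    if params.smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=params.smooth_sigma, mode="nearest")
    return _round_half_up(np.clip(img, 0.0, 255.0)).astype(np.uint8)


def _view_seed(base_seed: int, subject_index: int, view: str) -> int:
    # Deterministic per-view seed derivation; SeedSequence spawns keep the
    # streams independent of n_healthy/n_patient ordering details.
    view_index = VIEW_TAGS.index(view)
    ss = np.random.SeedSequence(entropy=base_seed, spawn_key=(subject_index, view_index))
    return int(ss.generate_state(1)[0])


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate the full synthetic cohort, a pure function of the config."""
    roi = config.centered_roi()
    records: list[SubjectRecord] = []
    labels = [HEALTHY] * config.n_healthy + [PATIENT] * config.n_patient
    for idx, label in enumerate(labels):
        params = config.params_for(label)
        views = {
            tag: (
                generate_texture(params, config.image_extent, _view_seed(config.seed, idx, tag)),
                roi,
            )
            for tag in VIEW_TAGS
        }
        records.append(SubjectRecord(subject_id=f"S{idx:04d}", label=label, views=views))
    return records


def save_cohort(records: list[SubjectRecord], config: CohortConfig, out_dir: str | Path) -> Path:
    """Serialize a cohort: one PNG per view, a manifest CSV and the config JSON."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for tag, (img, roi) in rec.views.items():
            name = f"{rec.subject_id}_{tag}.png"
            iio.imwrite(out / name, img)
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "label": rec.label,
                    "view": tag,
                    "image_path": name,
                    "roi_row": roi.top,
                    "roi_col": roi.left,
                    "roi_height": roi.height,
                    "roi_width": roi.width,
                }
            )
    import pandas as pd

    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    cfg = asdict(config)
    cfg["class_params"] = {k: asdict(v) for k, v in config.class_params.items()}
    (out / "cohort_config.json").write_text(json.dumps(cfg, indent=2))
    return manifest


def load_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    """Load a cohort previously written by :func:`save_cohort`."""
    import pandas as pd

    from .roi_preprocess import load_image

    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    records = []
    for subject_id, group in df.groupby("subject_id", sort=True):
        views = {}
        labels = set(group["label"])
        if len(labels) != 1:
            raise ValueError(f"inconsistent labels for subject {subject_id}")
        for _, row in group.iterrows():
            img = load_image(manifest_path.parent / row["image_path"])
            roi = ROISpec(
                top=int(row["roi_row"]),
                left=int(row["roi_col"]),
                height=int(row["roi_height"]),
                width=int(row["roi_width"]),
            )
            views[row["view"]] = (img, roi)
        records.append(SubjectRecord(subject_id=str(subject_id), label=labels.pop(), views=views))
    return records
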