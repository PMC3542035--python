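"""ROI-perturbation robustness protocol.

Two kinds of surface are produced over a perturbation grid (shift,
resize or rotation):

* feature mode — percentage error of each feature relative to the
  unperturbed ROI, ``100 * (w_pert - w_base) / w_base``;
* classification mode — TPR/SPC/ACC of a fixed trained model when every
  test-set ROI is perturbed identically.

Grid cells whose perturbed ROI would leave the image (or violate the
size bounds) are marked invalid, never silently dropped; cells whose
base feature is zero report an undefined sentinel (NaN value with status
``undefined_base``) rather than a bogus 0 %.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .discriminant_suite import (
    ConfusionCounts,
    LabeledSample,
    evaluate,
    fit_discriminant,
    split_cohort,
)
from .roi_preprocess import (
    AffinePerturbation,
    ROIBoundsError,
    ROISpec,
    extract_roi,
    median_filter3,
    perturb_roi,
    rotate_roi_content,
)
from .texture_features import extract_features

__all__ = [
    "ShiftGrid",
    "SizeGrid",
    "RotationGrid",
    "SensitivitySurface",
    "feature_error_surface",
    "classification_sensitivity_surface",
    "rotation_sensitivity_report",
]

STATUS_OK = "ok"
STATUS_INVALID = "invalid_roi"
STATUS_UNDEFINED = "undefined_base"


@dataclass(frozen=True)
class ShiftGrid:
    """Row/column offsets, default -20..20 step 1; must include 0."""

    dm_values: tuple[int, ...] = tuple(range(-20, 21))
    dn_values: tuple[int, ...] = tuple(range(-20, 21))

    def __post_init__(self) -> None:
        for axis in (self.dm_values, self.dn_values):
            if 0 not in axis:
                raise ValueError("shift grid must include the zero offset")
            if any(abs(v) > 20 for v in axis):
                raise ValueError("shift offsets are limited to +/-20 px")

    def cells(self) -> Iterable[tuple[tuple[int, int], AffinePerturbation]]:
        for dm in self.dm_values:
            for dn in self.dn_values:
                yield (dm, dn), AffinePerturbation(dm=dm, dn=dn)

    @property
    def zero_cell(self) -> tuple[int, int]:
        return (0, 0)


@dataclass(frozen=True)
class SizeGrid:
    """Height/width deltas relative to the base ROI; must include (0, 0).

    The resulting ROI side lengths must stay within [10, 90] px; the grid
    cannot verify that without the base ROI, so out-of-range results are
    flagged invalid per cell.
    """

    dM_values: tuple[int, ...] = tuple(range(-20, 21))
    dN_values: tuple[int, ...] = tuple(range(-20, 21))
    min_side: int = 10
    max_side: int = 90

    def __post_init__(self) -> None:
        if 0 not in self.dM_values or 0 not in self.dN_values:
            raise ValueError("size grid must include the zero delta")

    def cells(self) -> Iterable[tuple[tuple[int, int], AffinePerturbation]]:
        for dM in self.dM_values:
            for dN in self.dN_values:
                yield (dM, dN), AffinePerturbation(dM=dM, dN=dN)

    @property
    def zero_cell(self) -> tuple[int, int]:
        return (0, 0)


@dataclass(frozen=True)
class RotationGrid:
    """Rotation angles in degrees, default 0..180 step 1; must include 0."""

    angles: tuple[float, ...] = tuple(float(a) for a in range(181))

    def __post_init__(self) -> None:
        if 0 not in self.angles:
            raise ValueError("rotation grid must include angle 0")
        if any(not 0 <= a <= 180 for a in self.angles):
            raise ValueError("angles must lie in [0, 180] degrees")

    def cells(self) -> Iterable[tuple[tuple[float], AffinePerturbation]]:
        for a in self.angles:
            yield (a,), AffinePerturbation(phi=a)

    @property
    def zero_cell(self) -> tuple[float]:
        return (0.0,)


@dataclass
class SensitivitySurface:
    """Per-grid-cell values with validity status.

    ``values`` maps cell -> mapping of measure name (w1/w2/w3 or
    TPR/SPC/ACC) -> float (NaN when undefined); ``status`` maps cell ->
    one of the STATUS_* markers; ``base_value`` holds the unperturbed
    reference measures.
    """

    kind: str
    values: dict[tuple, dict[str, float]] = field(default_factory=dict)
    status: dict[tuple, str] = field(default_factory=dict)
    base_value: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cell, measures in self.values.items():
            for measure, value in measures.items():
                rows.append(
                    {
                        "cell": "/".join(str(c) for c in cell),
                        "measure": measure,
                        "value": value,
                        "status": self.status[cell],
                    }
                )
        return pd.DataFrame(rows)


def _roi_for_cell(
    base_roi: ROISpec,
    pert: AffinePerturbation,
    image_extent: tuple[int, int],
    size_bounds: Optional[tuple[int, int]] = None,
) -> ROISpec:
    roi = perturb_roi(base_roi, pert, image_extent)
    if size_bounds is not None:
        lo, hi = size_bounds
        if not (lo <= roi.height <= hi and lo <= roi.width <= hi):
            raise ROIBoundsError(
                f"perturbed ROI {roi.height}x{roi.width} leaves the [{lo}, {hi}] size range"
            )
    return roi


def _cell_window(
    image: np.ndarray,
    base_roi: ROISpec,
    pert: AffinePerturbation,
    size_bounds: Optional[tuple[int, int]],
) -> np.ndarray:
    """Extract the ROI content for one grid cell (shift/size or rotation)."""
    if pert.phi != 0.0:
        return rotate_roi_content(image, base_roi, pert.phi)
    roi = _roi_for_cell(base_roi, pert, image.shape, size_bounds)
    return extract_roi(image, roi)


def feature_error_surface(
    image: np.ndarray,
    base_roi: ROISpec,
    grid: ShiftGrid | SizeGrid | RotationGrid,
    prefilter: bool = True,
) -> SensitivitySurface:
    """Percentage feature errors over the grid for a single host image."""
    host = median_filter3(image) if prefilter else np.asarray(image)
    if not base_roi.inside(host.shape):
        raise ROIBoundsError("base ROI is outside the host image")
    size_bounds = (grid.min_side, grid.max_side) if isinstance(grid, SizeGrid) else None

    base = extract_features(extract_roi(host, base_roi))
    base_measures = {"w1": base.w1, "w2": float(base.w2), "w3": base.w3}
    surface = SensitivitySurface(kind="feature", base_value=base_measures)

    for cell, pert in grid.cells():
        try:
            window = _cell_window(host, base_roi, pert, size_bounds)
        except (ROIBoundsError, ValueError):
            surface.values[cell] = {k: float("nan") for k in base_measures}
            surface.status[cell] = STATUS_INVALID
            continue
        feats = extract_features(window)
        measured = {"w1": feats.w1, "w2": float(feats.w2), "w3": feats.w3}
        errors: dict[str, float] = {}
        undefined = False
        for key, base_val in base_measures.items():
            if base_val == 0.0:
                errors[key] = float("nan")
                undefined = True
            else:
                errors[key] = 100.0 * (measured[key] - base_val) / base_val
        surface.values[cell] = errors
        surface.status[cell] = STATUS_UNDEFINED if undefined else STATUS_OK
    return surface


def classification_sensitivity_surface(
    records,
    grid: ShiftGrid | SizeGrid | RotationGrid,
    variant: str,
    seed: int,
    retrain_per_cell: bool = False,
) -> SensitivitySurface:
    """TPR/SPC/ACC over the grid when every test ROI is perturbed identically.

    The model is trained once on unperturbed learning-partition features
    (measurement-error-at-diagnosis framing); ``retrain_per_cell``
    switches to retraining on equally perturbed training ROIs.  Cells
    whose perturbation is illegal for *any* test subject are masked
    invalid.
    """
    from .pipeline import cohort_to_samples  # local import avoids a cycle

    size_bounds = (grid.min_side, grid.max_side) if isinstance(grid, SizeGrid) else None

    filtered: dict[tuple[str, str], tuple[np.ndarray, ROISpec, str]] = {}
    for rec in records:
        for view, (img, roi) in rec.views.items():
            filtered[(rec.subject_id, view)] = (median_filter3(img), roi, rec.label)

    samples = cohort_to_samples(records, prefiltered=filtered)
    train, _val, test = split_cohort(samples, seed)
    model = fit_discriminant(train, variant)
    base_counts = evaluate(model, test)
    surface = SensitivitySurface(
        kind="classification",
        base_value={"TPR": base_counts.TPR, "SPC": base_counts.SPC, "ACC": base_counts.ACC},
    )

    test_keys = [(s.subject_id, s.view) for s in test]
    train_keys = [(s.subject_id, s.view) for s in train]

    def perturbed_samples(keys, originals):
        out = []
        for key, orig in zip(keys, originals):
            host, roi, label = filtered[key]
            window = _cell_window(host, roi, pert, size_bounds)
            out.append(
                LabeledSample(
                    features=extract_features(window),
                    label=label,
                    view=orig.view,
                    subject_id=orig.subject_id,
                )
            )
        return out

    for cell, pert in grid.cells():
        try:
            p_test = perturbed_samples(test_keys, test)
            cell_model = model
            if retrain_per_cell:
                cell_model = fit_discriminant(perturbed_samples(train_keys, train), variant)
            counts = evaluate(cell_model, p_test)
        except (ROIBoundsError, ValueError):
            surface.values[cell] = {"TPR": float("nan"), "SPC": float("nan"), "ACC": float("nan")}
            surface.status[cell] = STATUS_INVALID
            continue
        surface.values[cell] = {"TPR": counts.TPR, "SPC": counts.SPC, "ACC": counts.ACC}
        surface.status[cell] = STATUS_OK
    return surface


def rotation_sensitivity_report(
    image: np.ndarray, base_roi: ROISpec, angles: Optional[tuple[float, ...]] = None
) -> pd.DataFrame:
    """Per-angle percentage feature errors vs the 0-degree reference.

    Raises with the full list of offending angles if the rotated window
    overflows the host image anywhere on the grid.
    """
    grid = RotationGrid() if angles is None else RotationGrid(angles=tuple(angles))
    host = median_filter3(image)
    bad = []
    for (angle,), pert in grid.cells():
        try:
            rotate_roi_content(host, base_roi, angle)
        except ROIBoundsError:
            bad.append(angle)
    if bad:
        raise ROIBoundsError(f"rotated window exceeds image bounds at angles: {bad}")

    surface = feature_error_surface(image, base_roi, grid)
    rows = []
    for (angle,), errs in surface.values.items():
        rows.append({"angle": angle, **errs, "status": surface.status[(angle,)]})
    return pd.DataFrame(rows).sort_values("angle").reset_index(drop=True)
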