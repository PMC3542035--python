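"""End-to-end experiment orchestration: simulate -> features -> classify ->
baselines -> sensitivity -> report bundle."""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import baselines as bl
from .discriminant_suite import (
    VARIANTS,
    VIEW_GROUPS,
    LabeledSample,
    run_grouped_evaluation,
    split_cohort,
)
from .roi_preprocess import extract_roi, median_filter3
from .sensitivity import ShiftGrid, SizeGrid, classification_sensitivity_surface
from .synthetic_cohort import (
    CohortConfig,
    SubjectRecord,
    generate_cohort,
    load_cohort,
    save_cohort,
)
from .texture_features import extract_features

logger = logging.getLogger("thyrotex")

__all__ = ["ExperimentConfig", "cohort_to_samples", "stage_seed", "run_experiment"]


def stage_seed(seed: int, stage: str) -> int:
    """Fan the global seed out per stage via a stable name hash."""
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(stage.encode()),)).generate_state(1)[0])


def cohort_to_samples(
    records: list[SubjectRecord],
    prefiltered: Optional[dict] = None,
) -> list[LabeledSample]:
    """Median-filter every view image, crop its ROI and extract features.

    ``prefiltered`` optionally maps (subject_id, view) to an already
    filtered (image, roi, label) triple to avoid refiltering.
    """
    samples = []
    for rec in records:
        for view, (img, roi) in rec.views.items():
            if prefiltered is not None and (rec.subject_id, view) in prefiltered:
                host = prefiltered[(rec.subject_id, view)][0]
            else:
                host = median_filter3(img)
            feats = extract_features(extract_roi(host, roi))
            samples.append(
                LabeledSample(
                    features=feats, label=rec.label, view=view, subject_id=rec.subject_id
                )
            )
    return samples


def features_table(samples: list[LabeledSample]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "view": s.view,
                "label": s.label,
                "w1": s.features.w1,
                "w2": s.features.w2,
                "w3": s.features.w3,
            }
            for s in samples
        ]
    )


@dataclass
class ExperimentConfig:
    """Configuration of one end-to-end run."""

    seed: int
    output_dir: Path
    cohort: Optional[CohortConfig] = None
    manifest: Optional[Path] = None
    groups: tuple[str, ...] = tuple(VIEW_GROUPS)
    variants: tuple[str, ...] = VARIANTS
    run_classification: bool = True
    run_baselines: bool = True
    run_sensitivity: bool = False
    sensitivity_variant: str = "linear"
    sensitivity_step: int = 10
    retrain_per_cell: bool = False

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.cohort is None and self.manifest is None:
            raise ValueError("config needs either a synthetic cohort spec or a manifest path")
        if not (self.run_classification or self.run_baselines or self.run_sensitivity):
            raise ValueError("enable at least one of classification, baselines, sensitivity")

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        from .synthetic_cohort import TextureParams

        cohort = None
        if "cohort" in data and data["cohort"] is not None:
            c = dict(data["cohort"])
            if "class_params" in c:
                c["class_params"] = {
                    k: TextureParams(**v) for k, v in c["class_params"].items()
                }
            if "image_extent" in c:
                c["image_extent"] = tuple(c["image_extent"])
            if "roi_extent" in c:
                c["roi_extent"] = tuple(c["roi_extent"])
            cohort = CohortConfig(**c)
        kwargs = {k: v for k, v in data.items() if k != "cohort"}
        if "manifest" in kwargs and kwargs["manifest"] is not None:
            kwargs["manifest"] = Path(kwargs["manifest"])
        if "groups" in kwargs:
            kwargs["groups"] = tuple(kwargs["groups"])
        if "variants" in kwargs:
            kwargs["variants"] = tuple(kwargs["variants"])
        return cls(cohort=cohort, **kwargs)


def _stage(name: str):
    logger.info("stage=%s starting", name)


def run_experiment(config: ExperimentConfig) -> dict:
    """Run all enabled stages; write the report bundle; return the summary dict."""
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    _stage("simulate")
    try:
        if config.manifest is not None:
            records = load_cohort(config.manifest)
        else:
            records = generate_cohort(config.cohort)
            save_cohort(records, config.cohort, out / "cohort")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    _stage("features")
    try:
        samples = cohort_to_samples(records)
        features_table(samples).to_csv(out / "features.csv", index=False, float_format="%.8g")
    except Exception as exc:
        raise RuntimeError(f"stage 'features' failed: {exc}") from exc

    if config.run_classification:
        _stage("classify")
        try:
            table = run_grouped_evaluation(samples, stage_seed(config.seed, "classify"))
            table = table[table["group"].isin(config.groups) & table["variant"].isin(config.variants)]
            table.to_csv(out / "grouped_evaluation.csv", index=False, float_format="%.8g")
            summary["classification"] = {
                f"{r.group}/{r.variant}": r.ACC for r in table.itertuples()
            }
            best = {}
            for group, sub in table.groupby("group"):
                top = sub.loc[sub["ACC"].idxmax()]
                best[group] = {"variant": top["variant"], "ACC": float(top["ACC"])}
            summary["best_variant_by_group"] = best
        except Exception as exc:
            raise RuntimeError(f"stage 'classify' failed: {exc}") from exc

    if config.run_baselines:
        _stage("baseline")
        try:
            rois = [
                (extract_roi(median_filter3(img), roi), rec.label)
                for rec in records
                for _, (img, roi) in rec.views.items()
            ]
            sweep = bl.method1_threshold_sweep(rois)
            sweep.to_csv(out / "method1_sweep.csv", index=False, float_format="%.8g")
            summary["method1_best_acc"] = float(sweep["ACC"].max())

            train, val, test = split_cohort(samples, stage_seed(config.seed, "classify"))
            tree = bl.method2_fit(train, val, seed=stage_seed(config.seed, "baseline"))
            (out / "method2_tree.json").write_text(tree.to_json())
            correct = sum(bl.method2_predict(tree, s.features) == s.label for s in test)
            summary["method2_test_acc"] = correct / len(test)
            summary["method2_prune_level"] = tree.prune_level
        except Exception as exc:
            raise RuntimeError(f"stage 'baseline' failed: {exc}") from exc

    if config.run_sensitivity:
        _stage("sensitivity")
        try:
            step = config.sensitivity_step
            grids = {
                "shift": ShiftGrid(
                    dm_values=tuple(range(-20, 21, step)), dn_values=tuple(range(-20, 21, step))
                ),
                "size": SizeGrid(
                    dM_values=tuple(range(-20, 21, step)), dN_values=tuple(range(-20, 21, step))
                ),
            }
            for name, grid in grids.items():
                surface = classification_sensitivity_surface(
                    records,
                    grid,
                    config.sensitivity_variant,
                    stage_seed(config.seed, "classify"),
                    retrain_per_cell=config.retrain_per_cell,
                )
                surface.to_frame().to_csv(out / f"sensitivity_{name}.csv", index=False, float_format="%.8g")
                summary[f"sensitivity_{name}_base"] = surface.base_value
        except Exception as exc:
            raise RuntimeError(f"stage 'sensitivity' failed: {exc}") from exc

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
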