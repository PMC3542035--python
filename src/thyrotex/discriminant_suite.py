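"""Five discriminant-analysis variants over (w1, w2, w3) with TPR/SPC/ACC reporting.

Variants
--------
``linear``
    Gaussian discriminant with a pooled within-class covariance.
``diaglinear``
    As ``linear`` but the pooled covariance is diagonalized (naive Bayes).
``quadratic``
    Per-class covariance matrices.
``diagquadratic``
    Per-class diagonal covariances (naive Bayes).
``mahalanobis``
    Nearest class mean by Mahalanobis distance under each class's own
    covariance; no prior or determinant term enters the decision.

The positive class is ``patient``.  Prediction ties break toward
``healthy`` (deterministic, conservative for screening).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_cohort import HEALTHY, PATIENT, VIEW_TAGS
from .texture_features import FeatureVector

__all__ = [
    "VARIANTS",
    "VIEW_GROUPS",
    "LabeledSample",
    "DiscriminantModel",
    "ConfusionCounts",
    "split_cohort",
    "select_view_group",
    "fit_discriminant",
    "predict",
    "predict_many",
    "evaluate",
    "run_grouped_evaluation",
]

VARIANTS = ("linear", "diaglinear", "quadratic", "diagquadratic", "mahalanobis")

#: Seven view groupings: single views plus transverse, longitudinal and all-view pools.
VIEW_GROUPS: dict[str, tuple[str, ...]] = {
    "LO": ("LO",),
    "RO": ("RO",),
    "LRO": ("LO", "RO"),
    "LD": ("LD",),
    "RD": ("RD",),
    "RLD": ("LD", "RD"),
    "RLOD": VIEW_TAGS,
}

#: Ridge factor applied to singular covariance estimates.
RIDGE_LAMBDA = 1e-6

_CLASS_ORDER = (HEALTHY, PATIENT)  # healthy first => ties resolve to healthy


@dataclass(frozen=True)
class LabeledSample:
    features: FeatureVector
    label: str
    view: str
    subject_id: str

    def __post_init__(self) -> None:
        if self.view not in VIEW_TAGS:
            raise ValueError(f"view must be one of {VIEW_TAGS} (got {self.view!r})")
        if self.label not in _CLASS_ORDER:
            raise ValueError(f"label must be one of {_CLASS_ORDER} (got {self.label!r})")


@dataclass(frozen=True)
class DiscriminantModel:
    variant: str
    class_means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]  # pooled variants store it under each class key
    priors: dict[str, float]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @property
    def TPR(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else float("nan")

    @property
    def SPC(self) -> float:
        d = self.FP + self.TN
        return self.TN / d if d else float("nan")

    @property
    def ACC(self) -> float:
        return (self.TP + self.TN) / self.total if self.total else float("nan")


def split_cohort(
    samples: list[LabeledSample], seed: int
) -> tuple[list[LabeledSample], list[LabeledSample], list[LabeledSample]]:
    """Subject-level stratified random thirds (learning / validation / test).

    All views of a subject land in the same partition.  Within each class
    the partition sizes differ by at most one subject; remainders favour
    the learning, then the validation partition.
    """
    by_subject: dict[str, list[LabeledSample]] = {}
    subject_label: dict[str, str] = {}
    for s in samples:
        by_subject.setdefault(s.subject_id, []).append(s)
        subject_label[s.subject_id] = s.label

    rng = np.random.default_rng(seed)
    partitions: tuple[list[LabeledSample], ...] = ([], [], [])
    for label in _CLASS_ORDER:
        subjects = sorted(sid for sid, lab in subject_label.items() if lab == label)
        if len(subjects) < 3:
            raise ValueError(
                f"class {label!r} has {len(subjects)} subjects; need >= 3 to split into thirds"
            )
        order = rng.permutation(len(subjects))
        shuffled = [subjects[i] for i in order]
        # np.array_split puts remainder subjects in the earlier chunks.
        for part, chunk in zip(partitions, np.array_split(np.array(shuffled), 3)):
            for sid in chunk:
                part.extend(by_subject[sid])
    return partitions


def select_view_group(samples: list[LabeledSample], group: str) -> list[LabeledSample]:
    """Filter samples to one of the seven view groupings."""
    if group not in VIEW_GROUPS:
        raise ValueError(f"unknown view group {group!r}; expected one of {tuple(VIEW_GROUPS)}")
    allowed = set(VIEW_GROUPS[group])
    return [s for s in samples if s.view in allowed]


def _feature_matrix(samples: list[LabeledSample]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([s.features.as_array() for s in samples], dtype=float)
    y = np.array([s.label for s in samples])
    return X, y


def _regularize(cov: np.ndarray) -> np.ndarray:
    """Add a small ridge when the covariance is (near-)singular."""
    try:
        np.linalg.cholesky(cov)
        return cov
    except np.linalg.LinAlgError:
        pass
    d = cov.shape[0]
    ridge = RIDGE_LAMBDA * max(np.trace(cov) / d, 1.0)
    cov = cov + ridge * np.eye(d)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError("covariance not positive definite after regularization") from exc
    return cov


def fit_discriminant(train: list[LabeledSample], variant: str) -> DiscriminantModel:
    """Fit one discriminant variant on the learning samples.

    Class means are sample means; covariances use the n-1 denominator;
    pooled (within-class) covariance for the linear variants, per-class
    for the quadratic/mahalanobis ones; diagonal variants zero the
    off-diagonal entries; priors are empirical class frequencies.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    X, y = _feature_matrix(train)
    present = set(y)
    for label in _CLASS_ORDER:
        if label not in present:
            raise ValueError(f"class {label!r} absent from the training set")

    per_class = variant in ("quadratic", "diagquadratic", "mahalanobis")
    means: dict[str, np.ndarray] = {}
    covs: dict[str, np.ndarray] = {}
    priors: dict[str, float] = {}
    n_total = len(y)
    d = X.shape[1]

    pooled = np.zeros((d, d))
    for label in _CLASS_ORDER:
        Xk = X[y == label]
        nk = len(Xk)
        if per_class and nk < 4:
            raise ValueError(
                f"variant {variant!r} needs >= 4 samples per class "
                f"(class {label!r} has {nk})"
            )
        means[label] = Xk.mean(axis=0)
        priors[label] = nk / n_total
        centered = Xk - means[label]
        if per_class:
            covs[label] = centered.T @ centered / (nk - 1)
        else:
            pooled += centered.T @ centered

    if not per_class:
        pooled /= n_total - len(_CLASS_ORDER)
        covs = {label: pooled.copy() for label in _CLASS_ORDER}

    if variant in ("diaglinear", "diagquadratic"):
        covs = {label: np.diag(np.diag(c)) for label, c in covs.items()}
    covs = {label: _regularize(c) for label, c in covs.items()}
    return DiscriminantModel(variant=variant, class_means=means, covariances=covs, priors=priors)


def _scores(model: DiscriminantModel, x: np.ndarray) -> dict[str, float]:
    """Per-class decision scores; the predicted class maximizes the score."""
    scores = {}
    for label in _CLASS_ORDER:
        mu = model.class_means[label]
        cov = model.covariances[label]
        diff = x - mu
        maha2 = float(diff @ np.linalg.solve(cov, diff))
        if model.variant == "mahalanobis":
            scores[label] = -maha2
        else:
            sign, logdet = np.linalg.slogdet(cov)
            if sign <= 0:
                raise ValueError("covariance not positive definite")
            scores[label] = -0.5 * maha2 - 0.5 * logdet + np.log(model.priors[label])
    return scores


def predict(model: DiscriminantModel, features: FeatureVector | np.ndarray) -> str:
    """Classify one feature vector; exact score ties resolve to healthy."""
    x = features.as_array() if isinstance(features, FeatureVector) else np.asarray(features, float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite feature vector {x}")
    scores = _scores(model, x)
    # healthy first in _CLASS_ORDER, so ">" keeps healthy on ties
    best_label, best_score = None, -np.inf
    for label in _CLASS_ORDER:
        if scores[label] > best_score:
            best_label, best_score = label, scores[label]
    return best_label


def predict_many(model: DiscriminantModel, samples: list[LabeledSample]) -> list[str]:
    return [predict(model, s.features) for s in samples]


def evaluate(model: DiscriminantModel, test: list[LabeledSample]) -> ConfusionCounts:
    """Confusion counts on a test set; ``patient`` is the positive class."""
    if not test:
        raise ValueError("test set is empty")
    tp = tn = fp = fn = 0
    for sample in test:
        pred = predict(model, sample.features)
        if sample.label == PATIENT:
            if pred == PATIENT:
                tp += 1
            else:
                fn += 1
        else:
            if pred == HEALTHY:
                tn += 1
            else:
                fp += 1
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def run_grouped_evaluation(samples: list[LabeledSample], seed: int) -> pd.DataFrame:
    """Evaluate every (view group x variant) pair: 7 x 5 = 35 rows.

    The cohort is split into subject-level thirds once; models train on
    the learning partition and are scored on the test partition.  The
    validation partition is reserved for methods that need model
    selection.
    """
    train, _validation, test = split_cohort(samples, seed)
    rows = []
    for group in VIEW_GROUPS:
        g_train = select_view_group(train, group)
        g_test = select_view_group(test, group)
        for variant in VARIANTS:
            model = fit_discriminant(g_train, variant)
            counts = evaluate(model, g_test)
            rows.append(
                {
                    "group": group,
                    "variant": variant,
                    "TP": counts.TP,
                    "TN": counts.TN,
                    "FP": counts.FP,
                    "FN": counts.FN,
                    "TPR": counts.TPR,
                    "SPC": counts.SPC,
                    "ACC": counts.ACC,
                }
            )
    return pd.DataFrame(rows)
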