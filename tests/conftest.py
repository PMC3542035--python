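import numpy as np
import pytest

from thyrotex.discriminant_suite import LabeledSample
from thyrotex.synthetic_cohort import (
    HEALTHY,
    PATIENT,
    VIEW_TAGS,
    CohortConfig,
    generate_cohort,
)
from thyrotex.texture_features import FeatureVector


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject synthetic cohort (6 healthy / 6 patient), session-cached."""
    cfg = CohortConfig(n_healthy=6, n_patient=6, seed=7, image_extent=(110, 110), roi_extent=(50, 50))
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_samples(small_cohort):
    from thyrotex.pipeline import cohort_to_samples

    return cohort_to_samples(small_cohort)


def make_samples(rng, n_per_class=12, shift=2.0):
    """Cheap labeled samples from two shifted Gaussian feature clouds."""
    samples = []
    for idx in range(n_per_class * 2):
        label = HEALTHY if idx < n_per_class else PATIENT
        mu = np.array([0.003, 100.0, 20.0])
        if label == PATIENT:
            mu = mu + np.array([0.001, -shift * 10.0, shift * 3.0])
        x = mu + rng.normal(size=3) * np.array([0.0005, 3.0, 2.0])
        samples.append(
            LabeledSample(
                features=FeatureVector(w1=abs(float(x[0])), w2=int(np.clip(x[1], 0, 255)), w3=float(np.clip(x[2], 0, 100))),
                label=label,
                view=VIEW_TAGS[idx % 4],
                subject_id=f"T{idx:03d}",
            )
        )
    return samples


@pytest.fixture()
def gaussian_samples(rng):
    return make_samples(np.random.default_rng(42))
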