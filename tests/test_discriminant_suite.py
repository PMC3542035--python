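import numpy as np
import pytest
from scipy.stats import norm

from thyrotex.discriminant_suite import (
    VARIANTS,
    VIEW_GROUPS,
    ConfusionCounts,
    DiscriminantModel,
    LabeledSample,
    evaluate,
    fit_discriminant,
    predict,
    run_grouped_evaluation,
    select_view_group,
    split_cohort,
)
from thyrotex.synthetic_cohort import HEALTHY, PATIENT, VIEW_TAGS
from thyrotex.texture_features import FeatureVector

from conftest import make_samples


def fv(x):
    return FeatureVector(w1=float(x[0]), w2=float(x[1]), w3=float(x[2]))


def make_model(variant, means, covs, priors=None):
    priors = priors or {HEALTHY: 0.5, PATIENT: 0.5}
    return DiscriminantModel(
        variant=variant,
        class_means={k: np.asarray(v, float) for k, v in means.items()},
        covariances={k: np.asarray(v, float) for k, v in covs.items()},
        priors=priors,
    )


def subjects_with_views(labels):
    """One subject per label entry, all four views, trivial features."""
    samples = []
    for i, label in enumerate(labels):
        for view in VIEW_TAGS:
            samples.append(
                LabeledSample(
                    features=fv([0.001 * i, 50 + i, 10 + i]),
                    label=label,
                    view=view,
                    subject_id=f"S{i:03d}",
                )
            )
    return samples


class TestSplitCohort:
    def test_stratified_thirds(self):
        samples = subjects_with_views([HEALTHY] * 6 + [PATIENT] * 6)
        train, val, test = split_cohort(samples, seed=1)
        for part in (train, val, test):
            subjects = {s.subject_id for s in part}
            assert len(subjects) == 4
            assert len(part) == 16  # four views each
            labels = [next(s.label for s in part if s.subject_id == sid) for sid in subjects]
            assert labels.count(HEALTHY) == 2

    def test_subject_level_no_leakage(self):
        samples = subjects_with_views([HEALTHY] * 5 + [PATIENT] * 4)
        parts = split_cohort(samples, seed=3)
        seen = {}
        for pi, part in enumerate(parts):
            for s in part:
                assert seen.setdefault(s.subject_id, pi) == pi

    def test_determinism(self):
        samples = subjects_with_views([HEALTHY] * 6 + [PATIENT] * 6)
        a = split_cohort(samples, seed=5)
        b = split_cohort(samples, seed=5)
        for pa, pb in zip(a, b):
            assert [s.subject_id for s in pa] == [s.subject_id for s in pb]

    def test_remainder_distribution(self):
        # 7 healthy / 5 patient: per-class partition sizes differ by <= 1
        samples = subjects_with_views([HEALTHY] * 7 + [PATIENT] * 5)
        parts = split_cohort(samples, seed=2)
        for label, n in ((HEALTHY, 7), (PATIENT, 5)):
            sizes = [len({s.subject_id for s in p if s.label == label}) for p in parts]
            assert sum(sizes) == n
            assert max(sizes) - min(sizes) <= 1

    def test_too_few_subjects(self):
        samples = subjects_with_views([HEALTHY] * 2 + [PATIENT] * 3)
        with pytest.raises(ValueError, match="3"):
            split_cohort(samples, seed=0)


class TestSelectViewGroup:
    def test_rlod_all_views(self):
        samples = subjects_with_views([HEALTHY] * 5 + [PATIENT] * 5)
        assert len(select_view_group(samples, "RLOD")) == 40

    def test_empty_group(self):
        samples = [s for s in subjects_with_views([HEALTHY] * 3) if s.view == "LD"]
        assert select_view_group(samples, "LRO") == []

    def test_rld_is_union(self):
        samples = subjects_with_views([HEALTHY] * 4 + [PATIENT] * 4)
        rld = {id(s) for s in select_view_group(samples, "RLD")}
        union = {id(s) for s in select_view_group(samples, "LD")} | {
            id(s) for s in select_view_group(samples, "RD")
        }
        assert rld == union

    def test_unknown_tag(self):
        with pytest.raises(ValueError, match="unknown view group"):
            select_view_group([], "XYZ")


class TestFitDiscriminant:
    def cloud(self, rng, mu, n, label, start=0):
        out = []
        for i in range(n):
            x = np.asarray(mu) + rng.normal(size=3)
            out.append(LabeledSample(fv(x), label, VIEW_TAGS[i % 4], f"{label}{start + i}"))
        return out

    def test_pooled_identity(self, rng):
        r = np.random.default_rng(0)
        train = self.cloud(r, [0, 0, 0], 2000, HEALTHY) + self.cloud(r, [5, 5, 5], 2000, PATIENT)
        model = fit_discriminant(train, "linear")
        assert np.allclose(model.covariances[HEALTHY], np.eye(3), atol=0.15)
        assert np.allclose(model.covariances[HEALTHY], model.covariances[PATIENT])

    def test_diaglinear_strictly_diagonal(self, rng):
        r = np.random.default_rng(1)
        base = self.cloud(r, [0, 0, 0], 50, HEALTHY) + self.cloud(r, [3, 3, 3], 50, PATIENT)
        # correlate the features
        train = []
        for s in base:
            x = s.features.as_array()
            x[1] = x[0] * 2 + x[1] * 0.1
            train.append(LabeledSample(fv(x), s.label, s.view, s.subject_id))
        model = fit_discriminant(train, "diaglinear")
        for cov in model.covariances.values():
            off = cov - np.diag(np.diag(cov))
            assert np.all(off == 0)

    def test_quadratic_hand_computed_covariance(self):
        pts = {
            HEALTHY: [(0, 0, 0), (2, 0, 0), (0, 2, 0), (2, 2, 4)],
            PATIENT: [(10, 10, 10), (12, 10, 10), (10, 12, 10), (12, 12, 10)],
        }
        train = [
            LabeledSample(fv(p), label, VIEW_TAGS[i % 4], f"{label}{i}")
            for label, ps in pts.items()
            for i, p in enumerate(ps)
        ]
        model = fit_discriminant(train, "quadratic")
        X = np.array(pts[HEALTHY], float)
        expected = np.cov(X.T, ddof=1)
        assert np.allclose(model.covariances[HEALTHY], expected, atol=1e-12)

    def test_priors_empirical(self, rng):
        r = np.random.default_rng(2)
        train = self.cloud(r, [0, 0, 0], 30, HEALTHY) + self.cloud(r, [5, 5, 5], 10, PATIENT)
        model = fit_discriminant(train, "linear")
        assert model.priors[HEALTHY] == pytest.approx(0.75)
        assert sum(model.priors.values()) == pytest.approx(1.0)

    def test_missing_class(self, rng):
        r = np.random.default_rng(3)
        with pytest.raises(ValueError, match="absent"):
            fit_discriminant(self.cloud(r, [0, 0, 0], 10, HEALTHY), "linear")

    def test_singular_covariance_regularized(self):
        # all points identical per class -> zero covariance, ridge must rescue it
        train = [
            LabeledSample(fv([1, 2, 3]), HEALTHY, VIEW_TAGS[i % 4], f"h{i}") for i in range(5)
        ] + [LabeledSample(fv([4, 5, 6]), PATIENT, VIEW_TAGS[i % 4], f"p{i}") for i in range(5)]
        model = fit_discriminant(train, "quadratic")
        assert predict(model, fv([1, 2, 3])) == HEALTHY
        assert predict(model, fv([4, 5, 6])) == PATIENT

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="variant"):
            fit_discriminant([], "cubic")


class TestPredict:
    def test_nearest_mean_under_identity(self):
        model = make_model(
            "linear",
            {HEALTHY: [0, 0, 0], PATIENT: [2, 2, 2]},
            {HEALTHY: np.eye(3), PATIENT: np.eye(3)},
        )
        assert predict(model, np.array([1.1, 1.1, 1.1])) == PATIENT
        assert predict(model, np.array([0.9, 0.9, 0.9])) == HEALTHY

    def test_tie_breaks_healthy(self):
        model = make_model(
            "linear",
            {HEALTHY: [0, 0, 0], PATIENT: [2, 2, 2]},
            {HEALTHY: np.eye(3), PATIENT: np.eye(3)},
        )
        assert predict(model, np.array([1.0, 1.0, 1.0])) == HEALTHY

    def test_mahalanobis_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(3, 3))
        B = rng.normal(size=(3, 3))
        covs = {HEALTHY: A @ A.T + np.eye(3), PATIENT: B @ B.T + np.eye(3)}
        means = {HEALTHY: rng.normal(size=3), PATIENT: rng.normal(size=3)}
        model = make_model("mahalanobis", means, covs, priors={HEALTHY: 0.9, PATIENT: 0.1})
        inv = {k: np.linalg.inv(v) for k, v in covs.items()}
        for _ in range(500):
            x = rng.normal(scale=2.0, size=3)
            d2 = {k: (x - means[k]) @ inv[k] @ (x - means[k]) for k in means}
            expected = HEALTHY if d2[HEALTHY] <= d2[PATIENT] else PATIENT
            assert predict(model, x) == expected

    def test_linear_equals_mahalanobis_under_equal_priors_shared_cov(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            cov = A @ A.T + np.eye(3)
            means = {HEALTHY: rng.normal(size=3), PATIENT: rng.normal(size=3)}
            linear = make_model("linear", means, {HEALTHY: cov, PATIENT: cov.copy()})
            maha = make_model("mahalanobis", means, {HEALTHY: cov, PATIENT: cov.copy()})
            for _ in range(25):
                x = rng.normal(scale=2.0, size=3)
                assert predict(linear, x) == predict(maha, x)

    def test_non_finite_rejected(self):
        model = make_model(
            "linear", {HEALTHY: [0, 0, 0], PATIENT: [1, 1, 1]}, {HEALTHY: np.eye(3), PATIENT: np.eye(3)}
        )
        with pytest.raises(ValueError, match="non-finite"):
            predict(model, np.array([np.nan, 0, 0]))


class TestEvaluate:
    def perfect_model(self):
        return make_model(
            "linear",
            {HEALTHY: [0, 0, 0], PATIENT: [10, 10, 10]},
            {HEALTHY: np.eye(3), PATIENT: np.eye(3)},
        )

    def test_perfect_predictions(self):
        test = [
            LabeledSample(fv([10, 10, 10]), PATIENT, "LO", f"p{i}") for i in range(8)
        ] + [LabeledSample(fv([0, 0, 0]), HEALTHY, "LO", f"h{i}") for i in range(12)]
        counts = evaluate(self.perfect_model(), test)
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (8, 12, 0, 0)
        assert counts.ACC == 1.0

    def test_printed_formula_arithmetic(self):
        counts = ConfusionCounts(TP=19, TN=57, FP=3, FN=6)
        assert counts.TPR == pytest.approx(0.76)
        assert counts.SPC == pytest.approx(0.95)
        assert counts.ACC == pytest.approx(76 / 85)

    def test_all_healthy_predictor(self):
        model = make_model(
            "linear",
            {HEALTHY: [0, 0, 0], PATIENT: [100, 100, 100]},
            {HEALTHY: np.eye(3), PATIENT: np.eye(3)},
        )
        test = [
            LabeledSample(fv([0, 0, 0]), PATIENT, "LO", "p0"),
            LabeledSample(fv([0, 0, 0]), HEALTHY, "LO", "h0"),
        ]
        counts = evaluate(model, test)
        assert counts.TPR == 0.0 and counts.SPC == 1.0

    def test_undefined_metrics_are_nan(self):
        counts = ConfusionCounts(TP=0, TN=0, FP=0, FN=5)
        assert np.isnan(counts.SPC)
        assert counts.TPR == 0.0

    def test_permutation_invariance(self, rng):
        samples = make_samples(np.random.default_rng(4))
        model = fit_discriminant(samples, "linear")
        a = evaluate(model, samples)
        shuffled = list(samples)
        np.random.default_rng(5).shuffle(shuffled)
        b = evaluate(model, shuffled)
        assert (a.TP, a.TN, a.FP, a.FN) == (b.TP, b.TN, b.FP, b.FN)


class TestGroupedEvaluation:
    def test_35_rows_and_determinism(self):
        samples = subjects_with_views([HEALTHY] * 12 + [PATIENT] * 12)
        # add per-subject jitter so covariances are nonsingular
        rng = np.random.default_rng(6)
        jittered = [
            LabeledSample(
                fv(s.features.as_array() + rng.normal(scale=[0.0002, 1, 1])
                   + (0 if s.label == HEALTHY else np.array([0.002, -20, 15]))),
                s.label, s.view, s.subject_id,
            )
            for s in samples
        ]
        a = run_grouped_evaluation(jittered, seed=2)
        b = run_grouped_evaluation(jittered, seed=2)
        assert len(a) == 35
        assert set(a["group"]) == set(VIEW_GROUPS)
        assert set(a["variant"]) == set(VARIANTS)
        assert a.equals(b)


class TestBayesLimit:
    def test_linear_accuracy_matches_closed_form(self):
        # shared covariance, Mahalanobis separation 2 -> Bayes accuracy Phi(1)
        rng = np.random.default_rng(123)
        n = 2000
        mu_h, mu_p = np.zeros(3), np.array([2.0, 0.0, 0.0])
        train = []
        for i in range(2000):
            train.append(LabeledSample(fv(rng.normal(size=3) + mu_h), HEALTHY, "LO", f"h{i}"))
            train.append(LabeledSample(fv(rng.normal(size=3) + mu_p), PATIENT, "LO", f"p{i}"))
        model = fit_discriminant(train, "linear")
        correct = 0
        for i in range(n):
            label = HEALTHY if i % 2 == 0 else PATIENT
            mu = mu_h if label == HEALTHY else mu_p
            correct += predict(model, rng.normal(size=3) + mu) == label
        acc = correct / n
        expected = norm.cdf(1.0)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(acc - expected) < 3 * se
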