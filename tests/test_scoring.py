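"""Score prediction: exponential centroid model, systematic initialization,
beta-divergence k-means, and the end-to-end trial scorer."""

import numpy as np
import pytest

from ihcscore.errors import ControlOrderError, InsufficientDataError, ParameterError
from ihcscore.features import FeatureVector
from ihcscore.scoring import (
    CentroidSet,
    fit_two_term_exponential,
    init_centroids,
    kmeans_beta,
    score_trial,
)
from ihcscore.synthetic import PhantomSpec, generate_trial


def _fv(f1, f2, f3, image_id=""):
    return FeatureVector(image_id=image_id, f1=f1, f2=f2, f3=f3, n1=1.0, n2=f2)


def _beta_div_oracle(p, q):
    """Closed form of the element-wise divergence at beta = -0.5:
    2 p / sqrt(q) - 4 sqrt(p) + 2 sqrt(q), summed."""
    p = np.asarray(p, dtype=float)
    q = np.maximum(np.asarray(q, dtype=float), 1e-12)
    return float(np.sum(2 * p / np.sqrt(q) - 4 * np.sqrt(p) + 2 * np.sqrt(q)))


class TestExponentialFit:
    def test_recovers_single_exponential(self):
        x = np.linspace(0.1, 2.0, 12)
        y = 1.0 * np.exp(1.0 * x)
        a, b, c, d, ok = fit_two_term_exponential(x, y)
        assert ok
        pred = a * np.exp(b * x) + c * np.exp(d * x)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 1e-6

    def test_predicts_two_term_curve_at_held_out_points(self):
        x = np.linspace(0.1, 2.0, 15)
        true = lambda t: 0.5 * np.exp(2.0 * t) + 0.1 * np.exp(-1.0 * t)
        a, b, c, d, ok = fit_two_term_exponential(x, true(x))
        assert ok
        x_new = np.linspace(0.15, 1.95, 7)
        pred = a * np.exp(b * x_new) + c * np.exp(d * x_new)
        np.testing.assert_allclose(pred, true(x_new), rtol=1e-4)

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_two_term_exponential([0.1, 0.5, 1.0], [1.0, 2.0, 3.0])


class TestInitCentroids:
    def _features_on_curve(self, n=10):
        # f2, f3 decay exponentially in f1, as on real trials
        f1 = np.linspace(0.05, 1.0, n)
        feats = [
            _fv(x, float(np.exp(-2 * (x - 0.05)) * 10 + 1), float(np.exp(-2.5 * (x - 0.05)) * 20 + 1))
            for x in f1
        ]
        return feats

    def test_default_percentages_place_f1(self):
        feats = self._features_on_curve()
        cs = init_centroids(feats, idx1=0, idx5=9)
        f1_lo, f1_hi = feats[0].f1, feats[9].f1
        expected = f1_lo + np.array([0.15, 0.40, 0.70]) * (f1_hi - f1_lo)
        np.testing.assert_allclose(cs.centroids[1:4, 0], expected)
        np.testing.assert_allclose(cs.centroids[0], feats[0].as_array())
        np.testing.assert_allclose(cs.centroids[4], feats[9].as_array())

    def test_endpoint_percentages_coincide_with_controls(self):
        feats = self._features_on_curve()
        cs = init_centroids(feats, idx1=0, idx5=9, percentages=(0.0, 50.0, 100.0))
        assert cs.centroids[1, 0] == pytest.approx(feats[0].f1)
        assert cs.centroids[3, 0] == pytest.approx(feats[9].f1)

    def test_f1_strictly_increasing_with_default_percentages(self):
        feats = self._features_on_curve()
        cs = init_centroids(feats, idx1=0, idx5=9)
        assert np.all(np.diff(cs.centroids[:, 0]) > 0)
        assert cs.centroids.min() > 0

    def test_linear_feature_relation_recovered(self):
        # f2 linear in f1: the exponential model contains affine curves
        # (b -> 0 limit) or the fallback line is used; either way the
        # intermediate centroids must sit near the line
        f1 = np.linspace(0.1, 1.0, 10)
        feats = [_fv(x, 5.0 - 4.0 * x, 5.0 - 4.0 * x) for x in f1]
        cs = init_centroids(feats, idx1=0, idx5=9)
        expected = 5.0 - 4.0 * cs.centroids[1:4, 0]
        np.testing.assert_allclose(cs.centroids[1:4, 1], expected, rtol=0.05)

    def test_inverted_controls_raise(self):
        feats = self._features_on_curve()
        with pytest.raises(ControlOrderError):
            init_centroids(feats, idx1=9, idx5=0)

    def test_few_images_fall_back_to_interpolation(self):
        feats = self._features_on_curve(3)
        cs = init_centroids(feats, idx1=0, idx5=2)
        assert not cs.fit_ok[2] and not cs.fit_ok[3]
        # fallback interpolates between the control features
        lo, hi = feats[0], feats[2]
        frac = (cs.centroids[2, 0] - lo.f1) / (hi.f1 - lo.f1)
        assert cs.centroids[2, 1] == pytest.approx(lo.f2 + frac * (hi.f2 - lo.f2))


class TestKmeansBeta:
    def _centroids(self):
        cents = np.array(
            [
                [0.05, 10.0, 20.0],
                [0.20, 5.0, 9.0],
                [0.40, 2.5, 4.0],
                [0.65, 1.5, 2.0],
                [1.00, 1.0, 1.0],
            ]
        )
        return CentroidSet(centroids=cents, percentages=(15.0, 40.0, 70.0))

    def test_features_at_centroids_are_fixed_points(self):
        init = self._centroids()
        feats = [_fv(*row) for row in init.centroids]
        res = kmeans_beta(feats, init)
        np.testing.assert_array_equal(res.scores, [1, 2, 3, 4, 5])
        np.testing.assert_allclose(res.centroids, init.centroids)

    def test_controls_keep_their_scores(self):
        init = self._centroids()
        feats = [_fv(*init.centroids[0]), _fv(*init.centroids[4])]
        res = kmeans_beta(feats, init)
        np.testing.assert_array_equal(res.scores, [1, 5])
        assert res.divergences[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert res.divergences[1, 4] == pytest.approx(0.0, abs=1e-12)

    def test_assignment_matches_brute_force_oracle(self):
        """Independent reimplementation: closed-form beta=-0.5 divergence
        and an explicit assign/update loop."""
        init = self._centroids()
        rng = np.random.default_rng(9)
        feats = []
        for k in range(5):
            for _ in range(5):
                jitter = 1.0 + rng.uniform(-0.05, 0.05, size=3)
                feats.append(_fv(*(init.centroids[k] * jitter)))
        res = kmeans_beta(feats, init, beta=-0.5, max_iter=3)

        f = np.array([fv.as_array() for fv in feats])
        cents = init.centroids.copy()
        assign = np.full(len(feats), -1)
        for _ in range(3):
            new = np.array(
                [
                    int(np.argmin([_beta_div_oracle(fi, c) for c in cents]))
                    for fi in f
                ]
            )
            if np.array_equal(new, assign):
                break
            assign = new
            for j in range(5):
                members = f[assign == j]
                if members.size:
                    cents[j] = members.mean(axis=0)
        np.testing.assert_array_equal(res.scores, assign + 1)

    def test_tie_breaks_toward_lower_score(self):
        cents = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [9.0, 9.0, 9.0]])
        init = CentroidSet(centroids=cents, percentages=(50.0,))
        res = kmeans_beta([_fv(1.0, 1.0, 1.0)], init)
        assert res.scores[0] == 1

    def test_empty_cluster_keeps_centroid(self):
        init = self._centroids()
        feats = [_fv(*init.centroids[0]), _fv(*init.centroids[4])]
        res = kmeans_beta(feats, init)
        # middle clusters received no images and must stay where they were
        np.testing.assert_allclose(res.centroids[1:4], init.centroids[1:4])

    def test_iteration_cap_respected(self):
        init = self._centroids()
        rng = np.random.default_rng(10)
        feats = [
            _fv(*np.abs(rng.uniform(0.05, 2.0, size=3))) for _ in range(30)
        ]
        res = kmeans_beta(feats, init, max_iter=3)
        assert res.iterations_run <= 3


class TestScoreTrial:
    def test_scores_increase_with_dose(self, small_spec):
        trial = generate_trial(
            10, np.linspace(0.05, 1.2, 10), seed=21, base_spec=small_spec
        )
        res, _ = score_trial(trial.images, trial.idx1, trial.idx5)
        from scipy.stats import spearmanr

        rho = spearmanr(res.scores, trial.doses).statistic
        assert rho >= 0.9

    def test_two_image_trial_scores_controls(self, small_spec):
        trial = generate_trial(2, [0.05, 1.2], seed=22, base_spec=small_spec)
        res, _ = score_trial(trial.images, trial.idx1, trial.idx5)
        assert res.scores[trial.idx1] == 1
        assert res.scores[trial.idx5] == 5

    def test_deterministic_rerun(self, small_spec):
        trial = generate_trial(5, [0.05, 0.3, 0.6, 0.9, 1.2], seed=23, base_spec=small_spec)
        res1, _ = score_trial(trial.images, trial.idx1, trial.idx5)
        res2, _ = score_trial(trial.images, trial.idx1, trial.idx5)
        np.testing.assert_array_equal(res1.scores, res2.scores)
        np.testing.assert_array_equal(res1.divergences, res2.divergences)

    def test_identical_controls_rejected(self, small_spec):
        trial = generate_trial(2, [0.05, 1.2], seed=24, base_spec=small_spec)
        with pytest.raises(ParameterError):
            score_trial(trial.images, 1, 1)

    def test_constant_dose_trial_fails_control_order(self, small_spec):
        """Equal doses give equal control features; the designation is then
        inconsistent and must be reported, not silently scored."""
        trial = generate_trial(
            3, [0.5, 0.5, 0.5], seed=25, base_spec=small_spec, vary_structure=False
        )
        with pytest.raises(ControlOrderError):
            score_trial(trial.images, 0, 1)
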