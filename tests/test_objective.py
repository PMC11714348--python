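import numpy as np
import pytest

import sparseembed as se
from sparseembed.objective import _gradient, _pair_scatter, class_centroids, class_covariances

from conftest import planted_two_class


def loop_objective(values, labels, M, T, sparsity):
    """Naive per-pair, per-class oracle for the embedding objective."""
    R = labels.n_classes
    proj = values @ T
    dist = 0.0
    for f1 in range(R):
        for f2 in range(R):
            d = proj[labels.members(f1)].mean(axis=0) - proj[labels.members(f2)].mean(axis=0)
            dist += M.weights[f1, f2] * float(d @ d)
    dist /= R**2
    cov = 0.0
    for f in range(R):
        C = np.cov(proj[labels.members(f)], rowvar=False, ddof=1)
        cov += float(np.abs(np.atleast_2d(C)).sum())
    cov /= R
    l1 = float(np.abs(T).sum())
    return dist, cov, l1, dist - cov - sparsity * l1


class TestObjective:
    def test_hand_worked_value(self, hand_worked_instance):
        betas, labels, M, T = hand_worked_instance
        b = se.objective(betas, labels, M, T, sparsity=0.005)
        assert b.distance_term == pytest.approx(8.0)
        assert b.covariance_term == pytest.approx(2.0)
        assert b.l1_term == pytest.approx(1.0)
        assert b.total == pytest.approx(5.995)

    def test_zero_transform(self, hand_worked_instance):
        betas, labels, M, _ = hand_worked_instance
        b = se.objective(betas, labels, M, np.zeros((2, 1)), sparsity=0.005)
        assert (b.distance_term, b.covariance_term, b.l1_term, b.total) == (0, 0, 0, 0)

    def test_identical_centroids_zero_distance(self):
        rng = np.random.default_rng(0)
        scatter = rng.normal(size=(4, 3))
        raw = np.vstack([scatter, scatter])  # identical centroid and scatter
        betas = se.StandardizedBetaMatrix(raw, ("a", "b", "c"), standardized=False)
        labels = se.ParcelLabeling(
            np.repeat([0, 1], 4),
            (se.ParcelClass("A", "dorsal", 1), se.ParcelClass("A", "dorsal", 2)),
        )
        M = se.mask_custom(labels, [(0, 1)])
        T = rng.normal(size=(3, 2))
        assert se.objective(betas, labels, M, T).distance_term == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_loop_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n_classes = rng.integers(2, 5)
        m = rng.integers(2, 6)
        k = rng.integers(1, m + 1)
        per = rng.integers(2, 6)
        values = rng.normal(size=(n_classes * per, m))
        classes = tuple(se.ParcelClass("A", "dorsal", i + 1) for i in range(n_classes))
        labels = se.ParcelLabeling(np.repeat(np.arange(n_classes), per), classes)
        W = np.triu(rng.uniform(0, 2, size=(n_classes, n_classes)), k=1)
        W += W.T
        M = se.PairWeights(W)
        T = rng.normal(size=(m, k))
        betas = se.StandardizedBetaMatrix(values, tuple(f"c{i}" for i in range(m)), standardized=False)
        b = se.objective(betas, labels, M, T, sparsity=0.01)
        dist, cov, l1, total = loop_objective(values, labels, M, T, 0.01)
        assert b.distance_term == pytest.approx(dist, abs=1e-10)
        assert b.covariance_term == pytest.approx(cov, abs=1e-10)
        assert b.l1_term == pytest.approx(l1, abs=1e-10)
        assert b.total == pytest.approx(total, abs=1e-10)

    def test_distance_rotation_invariant_covariance_not(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(20, 4))
        values[:10] += rng.normal(size=4)
        classes = (se.ParcelClass("A", "dorsal", 1), se.ParcelClass("A", "dorsal", 2))
        labels = se.ParcelLabeling(np.repeat([0, 1], 10), classes)
        betas = se.StandardizedBetaMatrix(values, ("a", "b", "c", "d"), standardized=False)
        M = se.mask_custom(labels, [(0, 1)])
        T = rng.normal(size=(4, 2))
        theta = 0.7
        Rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        b1 = se.objective(betas, labels, M, T)
        b2 = se.objective(betas, labels, M, T @ Rot)
        assert b2.distance_term == pytest.approx(b1.distance_term, rel=1e-10)
        assert b2.covariance_term != pytest.approx(b1.covariance_term, rel=1e-6)
        assert b2.l1_term != pytest.approx(b1.l1_term, rel=1e-6)

    def test_column_negation_invariant(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(12, 3))
        classes = (se.ParcelClass("A", "dorsal", 1), se.ParcelClass("A", "dorsal", 2))
        labels = se.ParcelLabeling(np.repeat([0, 1], 6), classes)
        betas = se.StandardizedBetaMatrix(values, ("a", "b", "c"), standardized=False)
        M = se.mask_custom(labels, [(0, 1)])
        T = rng.normal(size=(3, 2))
        Tneg = T.copy()
        Tneg[:, 1] *= -1
        b1 = se.objective(betas, labels, M, T)
        b2 = se.objective(betas, labels, M, Tneg)
        assert b2.distance_term == pytest.approx(b1.distance_term, rel=1e-12)
        assert b2.covariance_term == pytest.approx(b1.covariance_term, rel=1e-12)
        assert b2.l1_term == pytest.approx(b1.l1_term, rel=1e-12)

    def test_shape_mismatch_rejected(self, hand_worked_instance):
        betas, labels, M, _ = hand_worked_instance
        with pytest.raises(ValueError, match="rows"):
            se.objective(betas, labels, M, np.ones((3, 1)))

    def test_subgradient_matches_finite_differences(self):
        rng = np.random.default_rng(7)
        values = rng.normal(size=(30, 4))
        values[:15] += 1.0
        classes = (se.ParcelClass("A", "dorsal", 1), se.ParcelClass("A", "dorsal", 2))
        labels = se.ParcelLabeling(np.repeat([0, 1], 15), classes)
        M = se.mask_custom(labels, [(0, 1)])
        cents = class_centroids(values, labels)
        covs = class_covariances(values, labels)
        A = _pair_scatter(cents, M)
        T = rng.normal(size=(4, 2)) + 0.5  # away from the |.| kinks
        grad, total = _gradient(T, A, covs, 2, 0.01)
        eps = 1e-6
        for i in range(4):
            for j in range(2):
                Tp, Tm = T.copy(), T.copy()
                Tp[i, j] += eps
                Tm[i, j] -= eps
                _, fp = _gradient(Tp, A, covs, 2, 0.01)
                _, fm = _gradient(Tm, A, covs, 2, 0.01)
                assert grad[i, j] == pytest.approx((fp - fm) / (2 * eps), abs=1e-4)


class TestFit:
    def test_reproducible_bitwise(self, small_synthetic):
        stack, labels, _ = small_synthetic
        M = se.mask_eccentricity(labels)
        betas = stack.standardized_average()
        cfg = se.FitConfig(k=1, seed=9)
        a = se.fit(betas, labels, M, config=cfg)
        b = se.fit(betas, labels, M, config=cfg)
        assert np.array_equal(a.components, b.components)
        assert a.converged and b.converged

    def test_huge_sparsity_kills_weights(self):
        betas, labels, M = planted_two_class(0)
        cfg = se.FitConfig(k=1, sparsity=1e6, seed=0, normalize_columns=False, max_iter=600)
        T = se.fit(betas, labels, M, config=cfg)
        assert np.abs(T.components).sum() < 1e-3

    def test_unit_columns_when_normalized(self):
        betas, labels, M = planted_two_class(1)
        T = se.fit(betas, labels, M, config=se.FitConfig(k=2, seed=1, max_iter=600))
        np.testing.assert_allclose(np.linalg.norm(T.components, axis=0), 1.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_planted_feature_recovered(self, seed):
        betas, labels, M = planted_two_class(seed, planted=3)
        T = se.fit(betas, labels, M, config=se.FitConfig(k=1, seed=seed, max_iter=600))
        assert int(np.argmax(np.abs(T.components[:, 0]))) == 3

    def test_isotropic_direction_matches_grid_oracle(self):
        # two classes with isotropic scatter: the optimum hugs the
        # centroid-difference direction; oracle = exhaustive unit-direction grid
        rng = np.random.default_rng(21)
        delta = np.array([1.0, 0.6])
        raw = np.vstack(
            [rng.normal(0, 0.5, size=(200, 2)), delta + rng.normal(0, 0.5, size=(200, 2))]
        )
        betas = se.StandardizedBetaMatrix(raw, ("a", "b"), standardized=False)
        labels = se.ParcelLabeling(
            np.repeat([0, 1], 200),
            (se.ParcelClass("A", "dorsal", 1), se.ParcelClass("A", "dorsal", 2)),
        )
        M = se.mask_custom(labels, [(0, 1)])
        fitted = se.fit(betas, labels, M, config=se.FitConfig(k=1, sparsity=0.0, seed=2))
        angles = np.linspace(0, np.pi, 3600, endpoint=False)
        best = max(
            angles,
            key=lambda a: se.objective(
                betas, labels, M, np.array([[np.cos(a)], [np.sin(a)]]), sparsity=0.0
            ).total,
        )
        fit_angle = np.arctan2(fitted.components[1, 0], fitted.components[0, 0]) % np.pi
        diff = abs(fit_angle - best) % np.pi
        diff = min(diff, np.pi - diff)
        assert np.degrees(diff) < 5.0

    def test_k_exceeding_m_rejected(self, hand_worked_instance):
        betas, labels, M, _ = hand_worked_instance
        std = se.standardize(betas.values + np.random.default_rng(0).normal(0, 0.01, betas.values.shape), betas.condition_names)
        with pytest.raises(ValueError, match="k"):
            se.fit(std, labels, M, config=se.FitConfig(k=5, seed=0))
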