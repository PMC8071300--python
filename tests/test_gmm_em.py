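"""Mixture-model machinery against brute-force and scikit-learn oracles."""

import numpy as np
import pytest

from lmrgait.gmm_em import (
    EmptyComponentError,
    GaussianComponent,
    GmmModel,
    Responsibilities,
    classify,
    e_step,
    fit_gmm,
    init_from_labels,
    init_random,
    log_likelihood,
    m_step,
    mvn_pdf,
)
from lmrgait.imu_core import DataError


def brute_mvn_pdf(x, mu, sigma):
    """Textbook density via explicit inverse and determinant."""
    x, mu, sigma = map(np.asarray, (x, mu, sigma))
    d = len(mu)
    dev = x - mu
    quad = dev @ np.linalg.inv(sigma) @ dev
    norm = 1.0 / np.sqrt(np.linalg.det(sigma) * (2 * np.pi) ** d)
    return norm * np.exp(-0.5 * quad)


def random_spd(rng, d):
    A = rng.normal(size=(d, d))
    return A @ A.T + d * np.eye(d)


def make_model(means, covs, weights):
    return GmmModel(
        components=[
            GaussianComponent(weight=w, mean=m, cov=c)
            for w, m, c in zip(weights, means, covs)
        ]
    )


class TestMvnPdf:
    def test_standard_normal_mode_1d(self):
        assert mvn_pdf(np.array([0.0]), np.array([0.0]), np.eye(1)) == pytest.approx(
            1 / np.sqrt(2 * np.pi), abs=1e-12
        )

    def test_standard_normal_mode_2d(self):
        val = mvn_pdf(np.zeros(2), np.zeros(2), np.eye(2))
        assert val == pytest.approx(1 / (2 * np.pi), abs=1e-12)

    def test_matches_brute_force_on_random_spd(self, rng):
        for _ in range(200):
            d = int(rng.integers(1, 5))
            mu = rng.normal(size=d)
            sigma = random_spd(rng, d)
            x = rng.normal(size=d)
            assert mvn_pdf(x, mu, sigma) == pytest.approx(
                brute_mvn_pdf(x, mu, sigma), rel=1e-10
            )

    def test_non_spd_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(DataError):
            mvn_pdf(np.zeros(2), np.zeros(2), bad)

    def test_integrates_to_one_1d(self):
        grid = np.linspace(-12, 12, 6001)
        dens = [mvn_pdf(np.array([g]), np.array([0.7]), 1.3 * np.eye(1)) for g in grid]
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-4)


class TestEStep:
    def test_identical_components_split_evenly(self, rng):
        model = make_model(
            [np.zeros(2), np.zeros(2)], [np.eye(2), np.eye(2)], [0.5, 0.5]
        )
        gamma = e_step(rng.normal(size=(20, 2)), model).gamma
        np.testing.assert_allclose(gamma, 0.5, atol=1e-12)

    def test_point_at_mean_of_distant_component(self):
        model = make_model(
            [np.zeros(2), np.full(2, 50.0)], [np.eye(2), np.eye(2)], [0.5, 0.5]
        )
        gamma = e_step(np.zeros((1, 2)), model).gamma[0]
        assert gamma[0] > 0.999

    def test_degenerate_prior(self, rng):
        model = make_model(
            [np.zeros(2), np.ones(2)], [np.eye(2), np.eye(2)], [1.0, 0.0]
        )
        gamma = e_step(rng.normal(size=(15, 2)), model).gamma
        np.testing.assert_allclose(gamma[:, 0], 1.0)

    def test_rows_sum_to_one(self, rng):
        model = make_model(
            [rng.normal(size=3) for _ in range(4)],
            [random_spd(rng, 3) for _ in range(4)],
            [0.1, 0.2, 0.3, 0.4],
        )
        gamma = e_step(rng.normal(size=(50, 3)), model).gamma
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-12)

    def test_survives_extreme_separation(self):
        # naive density products underflow here; log-space must not
        model = make_model(
            [np.zeros(1), np.full(1, 1e4)], [np.eye(1), np.eye(1)], [0.5, 0.5]
        )
        gamma = e_step(np.array([[0.0], [1e4]]), model).gamma
        assert gamma[0, 0] == pytest.approx(1.0)
        assert gamma[1, 1] == pytest.approx(1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            K, d, n = int(rng.integers(2, 4)), 2, 8
            weights = rng.dirichlet(np.ones(K))
            model = make_model(
                [rng.normal(size=d) * 3 for _ in range(K)],
                [random_spd(rng, d) for _ in range(K)],
                weights,
            )
            X = rng.normal(size=(n, d)) * 2
            gamma = e_step(X, model).gamma
            for i in range(n):
                dens = np.array(
                    [
                        c.weight * brute_mvn_pdf(X[i], c.mean, c.cov)
                        for c in model.components
                    ]
                )
                np.testing.assert_allclose(gamma[i], dens / dens.sum(), atol=1e-9)


class TestLogLikelihood:
    def test_single_component_reduction(self, rng):
        mu, sigma = rng.normal(size=2), random_spd(rng, 2)
        model = make_model([mu], [sigma], [1.0])
        X = rng.normal(size=(30, 2))
        direct = sum(np.log(brute_mvn_pdf(x, mu, sigma)) for x in X)
        assert log_likelihood(X, model) == pytest.approx(direct, rel=1e-9)

    def test_duplicating_data_doubles_value(self, rng):
        model = make_model(
            [np.zeros(2), np.ones(2)], [np.eye(2), np.eye(2)], [0.4, 0.6]
        )
        X = rng.normal(size=(20, 2))
        ll = log_likelihood(X, model)
        assert log_likelihood(np.vstack([X, X]), model) == pytest.approx(
            2 * ll, rel=1e-12
        )

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            K = int(rng.integers(1, 4))
            weights = rng.dirichlet(np.ones(K))
            model = make_model(
                [rng.normal(size=2) * 2 for _ in range(K)],
                [random_spd(rng, 2) for _ in range(K)],
                weights,
            )
            X = rng.normal(size=(10, 2))
            brute = sum(
                np.log(
                    sum(
                        c.weight * brute_mvn_pdf(x, c.mean, c.cov)
                        for c in model.components
                    )
                )
                for x in X
            )
            assert log_likelihood(X, model) == pytest.approx(brute, rel=1e-9)


def brute_m_step(X, gamma, ridge):
    """Loop-based restatement of the weighted-moment updates."""
    n, d = X.shape
    K = gamma.shape[1]
    mus, covs, weights = [], [], []
    for k in range(K):
        nk = sum(gamma[i, k] for i in range(n))
        mu = sum(gamma[i, k] * X[i] for i in range(n)) / nk
        cov = sum(
            gamma[i, k] * np.outer(X[i] - mu, X[i] - mu) for i in range(n)
        ) / nk + ridge * np.eye(d)
        mus.append(mu)
        covs.append(cov)
        weights.append(nk / n)
    return mus, covs, weights


class TestMStep:
    def test_one_hot_gamma_gives_group_means(self, rng):
        X = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, 30)
        labels[:3] = [0, 1, 2]  # every group nonempty
        gamma = np.zeros((30, 3))
        gamma[np.arange(30), labels] = 1.0
        model = m_step(X, Responsibilities(gamma=gamma), ridge=0.0)
        for k in range(3):
            np.testing.assert_allclose(
                model.components[k].mean, X[labels == k].mean(axis=0), atol=1e-12
            )

    def test_uniform_gamma_gives_uniform_weights(self, rng):
        X = rng.normal(size=(24, 2))
        gamma = np.full((24, 3), 1 / 3)
        model = m_step(X, Responsibilities(gamma=gamma))
        for comp in model.components:
            assert comp.weight == pytest.approx(1 / 3, abs=1e-12)

    def test_empty_component_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        gamma = np.zeros((10, 2))
        gamma[:, 0] = 1.0
        with pytest.raises(EmptyComponentError):
            m_step(X, Responsibilities(gamma=gamma))

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            n, d, K = 12, 2, 3
            X = rng.normal(size=(n, d)) * 3
            raw = rng.uniform(0.01, 1, size=(n, K))
            gamma = raw / raw.sum(axis=1, keepdims=True)
            model = m_step(X, Responsibilities(gamma=gamma), ridge=1e-6)
            mus, covs, weights = brute_m_step(X, gamma, 1e-6)
            for k in range(K):
                np.testing.assert_allclose(model.components[k].mean, mus[k], atol=1e-10)
                np.testing.assert_allclose(model.components[k].cov, covs[k], atol=1e-10)
                assert model.components[k].weight == pytest.approx(
                    weights[k], abs=1e-10
                )


def three_cluster_data(rng, n_per=300, sep=6.0):
    truth_means = np.array([[0.0, 0.0], [sep, 0.0], [0.0, sep]])
    X = np.vstack([rng.normal(m, 1.0, size=(n_per, 2)) for m in truth_means])
    y = np.repeat([0, 1, 2], n_per)
    return X, y, truth_means


class TestFitGmm:
    def test_single_gaussian_closed_form(self, rng):
        X = rng.normal(2.0, 1.5, size=(100, 2))
        init = make_model([np.zeros(2)], [np.eye(2)], [1.0])
        model, trace = fit_gmm(X, K=1, init=init, ridge=0.0)
        np.testing.assert_allclose(model.components[0].mean, X.mean(axis=0),
                                   atol=1e-10)
        np.testing.assert_allclose(
            model.components[0].cov, np.cov(X, rowvar=False, bias=True), atol=1e-10
        )

    def test_recovers_separated_clusters(self):
        rng = np.random.default_rng(42)
        X, y, truth_means = three_cluster_data(rng)
        model, _ = fit_gmm(X, K=3, init=init_from_labels(X, y))
        for k, m in enumerate(truth_means):
            assert np.linalg.norm(model.components[k].mean - m) < 0.2
            assert abs(model.components[k].weight - 1 / 3) < 0.05

    def test_agrees_with_sklearn_reference(self):
        # scikit-learn's GaussianMixture as an independent implementation
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(5)
        X, y, _ = three_cluster_data(rng, n_per=100)
        init = init_from_labels(X, y)
        ours, _ = fit_gmm(X, K=3, init=init, ridge=1e-6)
        ref = GaussianMixture(
            n_components=3,
            weights_init=np.full(3, 1 / 3),
            means_init=np.stack([c.mean for c in init.components]),
            precisions_init=np.stack(
                [np.linalg.inv(c.cov) for c in init.components]
            ),
            reg_covar=1e-6,
            tol=1e-6,
            random_state=0,
        ).fit(X)
        for k in range(3):
            np.testing.assert_allclose(
                ours.components[k].mean, ref.means_[k], atol=1e-3
            )
            assert ours.components[k].weight == pytest.approx(
                ref.weights_[k], abs=1e-3
            )

    def test_trace_monotone_on_random_data(self, rng):
        for _ in range(20):
            X = rng.normal(size=(120, 2)) * rng.uniform(0.5, 3)
            init = init_random(X, K=3, rng=rng)
            _, trace = fit_gmm(X, K=3, init=init, max_iter=40)
            diffs = np.diff(trace)
            assert np.all(diffs > -1e-8)

    def test_too_few_points_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        init = init_random(X, K=3, rng=rng)
        with pytest.raises(DataError):
            fit_gmm(X, K=3, init=init)


class TestClassify:
    def test_nearest_mode_wins(self):
        model = make_model(
            [np.zeros(2), np.full(2, 30.0)], [np.eye(2), np.eye(2)], [0.5, 0.5]
        )
        idx, gamma = classify(np.zeros(2), model)
        assert idx == 0 and gamma[0] > 0.999

    def test_exact_tie_breaks_to_first(self):
        model = make_model(
            [np.array([-1.0, 0]), np.array([1.0, 0])],
            [np.eye(2), np.eye(2)],
            [0.5, 0.5],
        )
        idx, gamma = classify(np.zeros(2), model)
        assert idx == 0
        assert gamma[0] == pytest.approx(gamma[1])

    def test_matches_brute_force_argmax(self, rng):
        model = make_model(
            [rng.normal(size=2) * 4 for _ in range(3)],
            [random_spd(rng, 2) for _ in range(3)],
            [0.2, 0.3, 0.5],
        )
        for _ in range(200):
            x = rng.normal(size=2) * 4
            idx, _ = classify(x, model)
            dens = [
                c.weight * brute_mvn_pdf(x, c.mean, c.cov)
                for c in model.components
            ]
            assert idx == int(np.argmax(dens))

    def test_component_permutation_permutes_labels(self, rng):
        comps = [
            GaussianComponent(1 / 3, rng.normal(size=2) * 5, random_spd(rng, 2))
            for _ in range(3)
        ]
        model = GmmModel(components=comps)
        perm = [2, 0, 1]
        permuted = GmmModel(components=[comps[p] for p in perm])
        for _ in range(30):
            x = rng.normal(size=2) * 5
            idx, _ = classify(x, model)
            pidx, _ = classify(x, permuted)
            assert perm[pidx] == idx


class TestInvariants:
    def test_weights_normalized_after_every_m_step(self, rng):
        X = rng.normal(size=(60, 2))
        model = init_random(X, K=3, rng=rng)
        for _ in range(5):
            model = m_step(X, e_step(X, model))
            weights = [c.weight for c in model.components]
            assert all(0.0 <= w <= 1.0 for w in weights)
            assert sum(weights) == pytest.approx(1.0, abs=1e-12)

    def test_invalid_responsibilities_rejected(self):
        with pytest.raises(DataError):
            Responsibilities(gamma=np.array([[0.5, 0.6]]))
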