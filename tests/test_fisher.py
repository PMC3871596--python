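"""Fisher metric field, local distances and geodesic graphs."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path

from fisonmf import (
    FisherGeodesicDistances,
    FisherMetric,
    MLPPosterior,
    generate_dataset,
    split_dataset,
)


class LogisticModel:
    """Two-class logistic posterior p(1|x) = sigmoid(w.x + b): closed-form J."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = float(b)

    def _p1(self, X):
        return 1.0 / (1.0 + np.exp(-(X @ self.w + self.b)))

    def predict_proba(self, X):
        X = np.atleast_2d(X)
        p1 = self._p1(X)
        return np.column_stack([1.0 - p1, p1])

    def log_proba_input_gradient(self, X):
        single = np.asarray(X).ndim == 1
        X = np.atleast_2d(X)
        p1 = self._p1(X)[:, None]
        G = np.stack([-p1 * self.w[None, :], (1.0 - p1) * self.w[None, :]], axis=1)
        if single:
            return G[0]
        return G


class TestFisherMatrix:
    def test_logistic_closed_form(self):
        # expanding J = sum_c p_c g_c g_c^T for two classes gives p(1-p) w w^T
        rng = np.random.default_rng(0)
        w = rng.normal(size=4)
        model = LogisticModel(w, b=0.3)
        fm = FisherMetric(model, epsilon=0.0)
        for _ in range(5):
            x = rng.normal(size=4)
            p = model.predict_proba(x)[0, 1]
            expected = p * (1 - p) * np.outer(w, w)
            assert np.abs(fm.fisher_matrix(x) - expected).max() < 1e-8

    def test_constant_posterior_gives_zero_matrix(self, trained_posterior):
        import copy

        m = copy.deepcopy(trained_posterior)
        m.coef_output_ = np.zeros_like(m.coef_output_)
        fm = FisherMetric(m, epsilon=0.0)
        J = fm.fisher_matrix(np.zeros(m.n_features_in_))
        assert np.abs(J).max() == 0.0

    def test_ridge_bounds_eigenvalues_below(self, trained_posterior):
        eps = 1e-4
        fm = FisherMetric(trained_posterior, epsilon=eps)
        x = np.random.default_rng(1).normal(size=trained_posterior.n_features_in_)
        vals = np.linalg.eigvalsh(fm.fisher_matrix(x))
        assert vals.min() >= eps - 1e-10


class TestLocalDistance:
    def test_coincident_points_have_zero_distance(self, trained_posterior):
        fm = FisherMetric(trained_posterior, 1e-6)
        x = np.random.default_rng(2).normal(size=trained_posterior.n_features_in_)
        assert fm.local_distance(x, x) == 0.0

    def test_symmetric_in_arguments(self, trained_posterior):
        fm = FisherMetric(trained_posterior, 1e-6)
        rng = np.random.default_rng(3)
        x1 = rng.normal(size=trained_posterior.n_features_in_)
        x2 = rng.normal(size=trained_posterior.n_features_in_)
        assert fm.local_distance(x1, x2) == pytest.approx(
            fm.local_distance(x2, x1), abs=1e-12
        )

    def test_identity_field_recovers_euclidean(self, constant_field_model):
        model = constant_field_model(np.eye(4))
        fm = FisherMetric(model, epsilon=0.0)
        rng = np.random.default_rng(4)
        x1, x2 = rng.normal(size=4), rng.normal(size=4)
        assert fm.local_distance(x1, x2) == pytest.approx(
            np.linalg.norm(x2 - x1), rel=1e-10
        )


class TestGeodesicMatrix:
    def test_shortest_path_properties(self, trained_posterior, separable_dataset):
        ds, _ = separable_dataset
        geo = FisherGeodesicDistances(trained_posterior).fit(ds.X.T[:25])
        D = geo.distances_
        assert np.allclose(np.diag(D), 0)
        assert np.allclose(D, D.T)
        assert np.all(D >= 0)
        assert np.all(np.isfinite(D))
        rng = np.random.default_rng(0)
        for _ in range(200):
            i, j, k = rng.integers(0, 25, size=3)
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-9

    def test_flat_metric_matches_mahalanobis_on_line_sample(
        self, constant_field_model
    ):
        rng = np.random.default_rng(0)
        M = rng.normal(size=(3, 3))
        A = M @ M.T + 0.5 * np.eye(3)
        model = constant_field_model(A)
        x0, x1 = rng.normal(size=3), rng.normal(size=3)
        t = np.linspace(0, 1, 40)[:, None]
        X = x0 + t * (x1 - x0)
        geo = FisherGeodesicDistances(
            model, n_neighbors=5, subdivisions=2, epsilon=0.0
        ).fit(X)
        maha = np.sqrt((x1 - x0) @ A @ (x1 - x0))
        assert abs(geo.distances_[0, -1] - maha) / maha < 0.05

    def test_single_subdivision_edge_equals_local_distance(
        self, constant_field_model
    ):
        model = constant_field_model(np.eye(2))
        fm = FisherMetric(model, 0.0)
        a, b = np.array([0.0, 0.0]), np.array([1.0, 2.0])
        w = fm.segment_lengths(a[None], b[None], subdivisions=1)[0]
        assert w == pytest.approx(fm.local_distance(a, b), abs=1e-12)

    def test_subdivision_refinement_converges_on_smooth_field(self):
        # quadrature convergence needs a smoothly varying metric; a gently
        # sloped logistic posterior provides one
        rng = np.random.default_rng(5)
        model = LogisticModel(rng.normal(size=4), b=0.1)
        fm = FisherMetric(model, 1e-8)
        A = rng.normal(size=(8, 4))
        B = rng.normal(size=(8, 4))
        w4 = fm.segment_lengths(A, B, subdivisions=4)
        w8 = fm.segment_lengths(A, B, subdivisions=8)
        assert np.all(np.abs(w8 - w4) / np.maximum(w4, 1e-12) < 0.02)

    def test_permutation_equivariance(self, trained_posterior, separable_dataset):
        ds, _ = separable_dataset
        X = ds.X.T[:20]
        D = FisherGeodesicDistances(trained_posterior).fit(X).distances_
        rng = np.random.default_rng(6)
        perm = rng.permutation(20)
        Dp = FisherGeodesicDistances(trained_posterior).fit(X[perm]).distances_
        assert np.abs(Dp - D[np.ix_(perm, perm)]).max() < 1e-9

    def test_single_point_yields_trivial_matrix(self, trained_posterior,
                                                separable_dataset):
        ds, _ = separable_dataset
        geo = FisherGeodesicDistances(trained_posterior).fit(ds.X.T[:1])
        assert geo.distances_.shape == (1, 1)
        assert geo.distances_[0, 0] == 0.0


class TestExtension:
    def test_duplicate_of_training_point_reproduces_its_row(
        self, trained_posterior, separable_dataset
    ):
        ds, _ = separable_dataset
        X = ds.X.T[:20]
        geo = FisherGeodesicDistances(trained_posterior).fit(X)
        ext = geo.transform(X[3][None, :])
        assert ext[0, 3] == pytest.approx(0.0, abs=1e-9)
        assert np.abs(ext[0] - geo.distances_[3]).max() < 1e-9

    def test_empty_new_set_gives_empty_matrix(self, trained_posterior,
                                              separable_dataset):
        ds, _ = separable_dataset
        geo = FisherGeodesicDistances(trained_posterior).fit(ds.X.T[:5])
        assert geo.transform(np.empty((0, ds.n_points))).shape == (0, 5)

    def test_matches_augmented_graph_dijkstra(self, constant_field_model):
        # independent oracle: add the new point's attachment edges to the
        # training graph and run a real shortest-path solver from it
        model = constant_field_model(np.eye(3))
        for seed in range(3):
            rng = np.random.default_rng(seed)
            P = rng.normal(size=(30, 3))
            new = rng.normal(size=(4, 3))
            geo = FisherGeodesicDistances(
                model, n_neighbors=10, subdivisions=1, epsilon=0.0
            ).fit(P)
            ext = geo.transform(new)
            n = 30
            W = np.linalg.norm(P[:, None] - P[None], axis=2)
            order = np.argsort(W + np.diag(np.full(n, np.inf)), axis=1)
            mask = np.zeros((n, n), bool)
            mask[np.repeat(np.arange(n), 10), order[:, :10].ravel()] = True
            mask |= mask.T
            mst = minimum_spanning_tree(W).toarray()
            mask |= (mst + mst.T) > 0
            for x, row in zip(new, ext):
                w = np.linalg.norm(P - x, axis=1)
                att = np.argsort(w)[:10]
                g = np.zeros((n + 1, n + 1))
                g[:n, :n] = np.where(mask, W, 0)
                g[n, att] = w[att]
                g[att, n] = w[att]
                D = shortest_path(
                    coo_matrix(g).tocsr(), method="D", directed=False
                )
                assert np.abs(D[n, :n] - row).max() < 1e-9


class TestMetricAmplification:
    def test_between_class_distances_amplified_over_within(self, ste_prototypes):
        """Class-separating directions expand; uninformative ones compress."""
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ds, _ = generate_dataset(
                ste_prototypes, {"A2": 15, "ME": 15}, noise_sd=0.01,
                overlap=0.0, seed=seed,
            )
            tr, ho = split_dataset(ds, seed=seed)
            mlp = MLPPosterior(random_state=seed, max_iter=200)
            mlp.fit(tr.X.T, tr.labels, ho.X.T, ho.labels)
            geo = FisherGeodesicDistances(mlp).fit(ds.X.T)
            D = geo.distances_
            a = ds.labels.astype(str) == "A2"
            E = np.linalg.norm(
                ds.X.T[:, None] - ds.X.T[None], axis=2
            )
            between = D[np.ix_(a, ~a)].mean() / max(E[np.ix_(a, ~a)].mean(), 1e-12)
            within = (
                D[np.ix_(a, a)].sum() + D[np.ix_(~a, ~a)].sum()
            ) / max(E[np.ix_(a, a)].sum() + E[np.ix_(~a, ~a)].sum(), 1e-12)
            hits += between > within
        assert hits >= 0.9 * n_seeds
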