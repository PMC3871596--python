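"""Fisher information metric in data space and geodesic distance graphs.

For a probabilistic classifier with posteriors ``p(c | x)`` the local
Fisher information matrix is

    J(x) = sum_c p(c | x) * g_c(x) g_c(x)^T + eps * I,
    g_c(x) = grad_x log p(c | x),

a symmetric PSD quadratic form that stretches directions along which the
predicted class changes rapidly and compresses uninformative ones.  The
local distance between nearby points is ``sqrt(dx^T J(m) dx)`` with J
evaluated at the segment midpoint.  Geodesic distances between arbitrary
spectra are approximated by shortest paths on a k-nearest-neighbor graph
whose edge weights are path integrals of the local metric along straight
segments (summed over a fixed number of subdivisions); a minimum-spanning-
tree over local distances is unioned in so the graph is always connected.

With two classes the raw J has rank one at every point, so a small ridge
``eps`` (scaled to the mean diagonal of J over the training set) keeps the
metric positive definite.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from sklearn.base import BaseEstimator

from .posterior import MLPPosterior

__all__ = ["FisherMetric", "FisherGeodesicDistances"]


class FisherMetric:
    """Evaluate J(x) and local quadratic distances for a posterior model."""

    def __init__(self, model: MLPPosterior, epsilon: float = 0.0):
        if epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        self.model = model
        self.epsilon = float(epsilon)

    def fisher_matrix(self, x: np.ndarray) -> np.ndarray:
        """Full d x d Fisher information matrix at one point."""
        x = np.asarray(x, dtype=float)
        G = self.model.log_proba_input_gradient(x)        # (C, d)
        if not np.all(np.isfinite(G)):
            bad = int(np.flatnonzero(~np.isfinite(G).all(axis=1))[0])
            raise FloatingPointError(
                f"non-finite log-posterior gradient for class index {bad}"
            )
        p = self.model.predict_proba(x)[0]                # (C,)
        J = (G.T * p) @ G
        if self.epsilon > 0:
            J = J + self.epsilon * np.eye(J.shape[0])
        return J

    def quadratic_form(self, mid: np.ndarray, delta: np.ndarray) -> np.ndarray:
        """``delta^T J(mid) delta`` for batches of midpoints/offsets.

        Never materializes J: uses ``sum_c p_c (g_c . delta)^2``.
        ``mid`` and ``delta`` are (m, d); returns (m,).
        """
        mid = np.atleast_2d(mid)
        delta = np.atleast_2d(delta)
        G = self.model.log_proba_input_gradient(mid)      # (m, C, d)
        P = self.model.predict_proba(mid)                 # (m, C)
        proj = np.einsum("mcd,md->mc", G, delta)
        q = np.einsum("mc,mc->m", P, proj**2)
        if self.epsilon > 0:
            q = q + self.epsilon * np.einsum("md,md->m", delta, delta)
        return q

    def local_distance(self, x1: np.ndarray, x2: np.ndarray) -> float:
        """Metric length of the chord x1 -> x2 under J at the midpoint."""
        x1 = np.asarray(x1, dtype=float)
        x2 = np.asarray(x2, dtype=float)
        if x1.shape != x2.shape:
            raise ValueError("x1 and x2 must have the same dimension")
        mid = 0.5 * (x1 + x2)
        q = self.quadratic_form(mid[None, :], (x2 - x1)[None, :])[0]
        return float(np.sqrt(max(q, 0.0)))

    def segment_lengths(
        self, A: np.ndarray, B: np.ndarray, subdivisions: int = 4
    ) -> np.ndarray:
        """Path-integral lengths of straight segments, batched.

        ``A`` and ``B`` are (m, d) endpoint arrays; each segment is split
        into ``subdivisions`` pieces and the local midpoint-rule length of
        each piece is summed (second-order accurate quadrature of the
        geodesic path integral along the chord).
        """
        A = np.atleast_2d(np.asarray(A, dtype=float))
        B = np.atleast_2d(np.asarray(B, dtype=float))
        if subdivisions < 1:
            raise ValueError("subdivisions must be >= 1")
        m = A.shape[0]
        total = np.zeros(m)
        step = (B - A) / subdivisions
        for s in range(subdivisions):
            mid = A + (s + 0.5) * step
            q = self.quadratic_form(mid, step)
            total += np.sqrt(np.maximum(q, 0.0))
        return total


class FisherGeodesicDistances(BaseEstimator):
    """Graph approximation of pairwise geodesic Fisher distances.

    Parameters
    ----------
    model : MLPPosterior
        Fitted posterior model supplying the metric.
    n_neighbors : int, default=10
        Neighborhood size of the k-NN graph (by local Fisher distance).
    subdivisions : int, default=4
        Segments per edge in the path-integral quadrature.
    epsilon : float or "auto", default="auto"
        Ridge added to J; "auto" uses 1e-6 x the mean diagonal of J over
        the training points.

    Attributes
    ----------
    distances_ : ndarray of shape (n, n)
        Symmetric geodesic distance matrix (zero diagonal, triangle
        inequality by shortest-path construction).
    local_weights_ : ndarray of shape (n, n)
        All-pairs chord lengths (path-integral edge weights).
    epsilon_ : float
        Ridge actually used.
    """

    def __init__(
        self,
        model: MLPPosterior,
        n_neighbors: int = 10,
        subdivisions: int = 4,
        epsilon: float | str = "auto",
    ):
        self.model = model
        self.n_neighbors = n_neighbors
        self.subdivisions = subdivisions
        self.epsilon = epsilon

    def _resolve_epsilon(self, X: np.ndarray) -> float:
        if self.epsilon != "auto":
            return float(self.epsilon)
        G = self.model.log_proba_input_gradient(X)        # (n, C, d)
        P = self.model.predict_proba(X)
        # mean over points of trace(J)/d  =  mean_c p_c |g_c|^2 / d
        tr = np.einsum("nc,ncd,ncd->n", P, G, G) / X.shape[1]
        return 1e-6 * float(np.mean(tr))

    def fit(self, X: np.ndarray, y=None) -> "FisherGeodesicDistances":
        """Compute the all-pairs geodesic matrix for rows of ``X``."""
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < 1:
            raise ValueError("need at least one point")
        self.train_X_ = X
        self.epsilon_ = self._resolve_epsilon(X)
        self.metric_ = FisherMetric(self.model, self.epsilon_)
        if n == 1:
            self.local_weights_ = np.zeros((1, 1))
            self.distances_ = np.zeros((1, 1))
            return self

        iu, ju = np.triu_indices(n, k=1)
        w = self.metric_.segment_lengths(X[iu], X[ju], self.subdivisions)
        W = np.zeros((n, n))
        W[iu, ju] = w
        W += W.T
        self.local_weights_ = W

        k = min(self.n_neighbors, n - 1)
        mask = np.zeros((n, n), dtype=bool)
        order = np.argsort(W + np.diag(np.full(n, np.inf)), axis=1)
        rows = np.repeat(np.arange(n), k)
        mask[rows, order[:, :k].ravel()] = True
        mask |= mask.T                                    # symmetric k-NN

        # MST over local distances guarantees connectivity
        mst = minimum_spanning_tree(W).toarray()
        mask |= (mst + mst.T) > 0

        graph = coo_matrix((W[mask], np.nonzero(mask)), shape=(n, n))
        D = shortest_path(graph.tocsr(), method="D", directed=False)
        self.distances_ = 0.5 * (D + D.T)
        np.fill_diagonal(self.distances_, 0.0)
        return self

    def transform(self, X_new: np.ndarray) -> np.ndarray:
        """Geodesic distances from new points to every training point.

        Each new point is attached to its ``n_neighbors`` nearest training
        points by chord length; its distance to training point ``j`` is the
        minimum over attachments ``a`` of ``w(new, a) + D[a, j]``.
        Training-to-training distances are unchanged.
        """
        if not hasattr(self, "distances_"):
            raise RuntimeError("fit must be called before transform")
        X_new = np.asarray(X_new, dtype=float)
        if X_new.size == 0:
            return np.zeros((0, self.train_X_.shape[0]))
        X_new = np.atleast_2d(X_new)
        n = self.train_X_.shape[0]
        m = X_new.shape[0]
        k = min(self.n_neighbors, n)
        out = np.empty((m, n))
        for i in range(m):
            A = np.repeat(X_new[i][None, :], n, axis=0)
            w = self.metric_.segment_lengths(A, self.train_X_, self.subdivisions)
            att = np.argsort(w)[:k]
            out[i] = np.min(w[att][:, None] + self.distances_[att, :], axis=0)
        return out
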