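"""Convex non-negative matrix factorization with K-means initialization.

Convex-NMF factorizes a (possibly mixed-sign) data matrix ``X`` of shape
``d x n`` as ``X ~ X W H`` with element-wise non-negative ``W`` (n x k, the
*unmixing* matrix) and ``H`` (k x n, the *mixing* matrix).  The sources
``S = X W`` are convex-like combinations of observed cases and therefore
interpretable as cluster centroids or class prototypes — and, unlike plain
NMF, they may carry negative values where the data do (long-echo-time
spectra with inverted doublets).

Optimization uses the multiplicative updates of Ding, Li & Jordan, driven
by the positive and negative parts of the Gram matrix ``X^T X``; both
updates are descent steps for the Frobenius reconstruction error from any
strictly positive initialization.  Initialization follows the K-means
recipe: cluster the cases, build the one-hot indicator matrix G, and set
``H0 = (G + 0.2 E)^T`` and ``W0 = (G + 0.2 E) Dn^{-1}`` with ``Dn`` the
diagonal matrix of cluster sizes.  Iteration stops when the relative change
of the reconstruction error drops below 1e-5 (the tolerance is exposed, and
an absolute-change mode is available).

The estimator follows the sklearn convention (rows are samples); the data
matrix above is the transpose of the ``X`` passed to :meth:`ConvexNMF.fit`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans

__all__ = ["positive_part", "negative_part", "kmeans_init", "ConvexNMF"]

_FLOOR = 1e-12  # denominator floor against 0/0 in multiplicative updates


def positive_part(M: np.ndarray) -> np.ndarray:
    """Entries > 0 kept, the rest zeroed."""
    M = np.asarray(M, dtype=float)
    return np.where(M > 0, M, 0.0)


def negative_part(M: np.ndarray) -> np.ndarray:
    """Magnitudes of entries < 0 (a non-negative matrix), the rest zeroed.

    Satisfies ``M = positive_part(M) - negative_part(M)`` exactly.
    """
    M = np.asarray(M, dtype=float)
    return np.where(M < 0, -M, 0.0)


def kmeans_init(
    X: np.ndarray, k: int, restarts: int = 10, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """K-means initialization of (W0, H0) for a d x n data matrix.

    Clusters the columns of ``X`` (best of ``restarts`` by within-cluster
    sum of squares), forms the n x k one-hot indicator ``G``, and returns

        W0 = (G + 0.2 E) Dn^{-1},   H0 = (G + 0.2 E)^T,

    with ``E`` all ones and ``Dn`` the diagonal of cluster sizes.  Both
    factors are strictly positive.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[1]
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    assign = km.fit_predict(X.T)
    G = np.zeros((n, k))
    G[np.arange(n), assign] = 1.0
    sizes = G.sum(axis=0)
    H0 = (G + 0.2).T
    W0 = (G + 0.2) / sizes[None, :]
    return W0, H0


class ConvexNMF(TransformerMixin, BaseEstimator):
    """Convex-NMF estimator (sklearn orientation: samples as rows).

    Parameters
    ----------
    n_components : int
        Number of sources k.
    tol : float, default=1e-5
        Convergence threshold on the change of the Frobenius
        reconstruction error between successive iterations.
    tol_mode : {"relative", "absolute"}, default="relative"
        Whether ``tol`` applies to the relative or absolute change.
    max_iter : int, default=2000
    restarts : int, default=10
        K-means restarts for the initialization.
    random_state : int or None
        Seed of the K-means initialization (the updates themselves are
        deterministic).

    Attributes
    ----------
    W_ : ndarray (n, k)
        Non-negative unmixing matrix.
    H_ : ndarray (k, n)
        Non-negative mixing matrix (per-case source weights in columns).
    sources_ : ndarray (d, k)
        ``S = X W`` in the d x n data orientation.
    components_ : ndarray (k, d)
        sklearn-style alias, ``sources_.T``.
    objective_trace_ : list of float
        Frobenius reconstruction error per iteration (non-increasing up to
        1e-8 slack).
    converged_ : bool
    """

    def __init__(
        self,
        n_components: int = 2,
        tol: float = 1e-5,
        tol_mode: str = "relative",
        max_iter: int = 2000,
        restarts: int = 10,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.tol = tol
        self.tol_mode = tol_mode
        self.max_iter = max_iter
        self.restarts = restarts
        self.random_state = random_state

    # ------------------------------------------------------------------
    @staticmethod
    def _updates(Yp, Ym, W, H):
        """One round of the multiplicative Convex-NMF updates.

        ``Yp``/``Ym`` are the positive/negative parts of the Gram matrix
        X^T X.  G = H^T is updated first, then W.
        """
        G = H.T
        num = Yp @ W + G @ (W.T @ Ym @ W)
        den = Ym @ W + G @ (W.T @ Yp @ W)
        G = G * np.sqrt(num / np.maximum(den, _FLOOR))
        num = Yp @ G + Ym @ W @ (G.T @ G)
        den = Ym @ G + Yp @ W @ (G.T @ G)
        W = W * np.sqrt(num / np.maximum(den, _FLOOR))
        return W, G.T

    @staticmethod
    def _recon_error(X, W, H):
        return float(np.linalg.norm(X - X @ W @ H, "fro"))

    def _fit_matrix(self, X, W, H):
        """Run updates on a d x n matrix from a strictly positive init."""
        Y = X.T @ X
        Yp, Ym = positive_part(Y), negative_part(Y)
        err = self._recon_error(X, W, H)
        trace = [err]
        converged = False
        for it in range(self.max_iter):
            W, H = self._updates(Yp, Ym, W, H)
            new_err = self._recon_error(X, W, H)
            if not np.isfinite(new_err):
                raise FloatingPointError(
                    f"non-finite reconstruction error at iteration {it + 1}"
                )
            trace.append(new_err)
            change = err - new_err
            scale = err if self.tol_mode == "relative" else 1.0
            err = new_err
            if abs(change) <= self.tol * max(scale, _FLOOR):
                converged = True
                break
        return W, H, trace, converged

    def fit(self, X: np.ndarray, y=None) -> "ConvexNMF":
        """Factorize ``X`` (rows are cases, columns are features)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        V = X.T                                   # d x n data orientation
        W0, H0 = kmeans_init(
            V, self.n_components, restarts=self.restarts, seed=self.random_state
        )
        W, H, trace, converged = self._fit_matrix(V, W0, H0)
        self.W_, self.H_ = W, H
        self.sources_ = V @ W
        self.components_ = self.sources_.T
        self.objective_trace_ = trace
        self.converged_ = converged
        self.train_data_ = V
        self.n_features_in_ = X.shape[1]
        return self

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        """Fit and return the per-case mixing weights, shape (n, k)."""
        return self.fit(X).H_.T

    def transform(self, X_new: np.ndarray, tol=None, max_iter=None) -> np.ndarray:
        """Mixing weights of new cases under the *fixed* trained sources.

        Iterates the H-only multiplicative update (sources held fixed at
        ``S = X_train W``) until the reconstruction-error change falls
        below ``tol`` (the fit's rule by default).  Returns (m, k).
        """
        if not hasattr(self, "W_"):
            raise RuntimeError("fit must be called before transform")
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.n_features_in_:
            raise ValueError("feature-count mismatch with the fitted model")
        tol = self.tol if tol is None else tol
        max_iter = self.max_iter if max_iter is None else max_iter
        V_new = X_new.T                           # d x m
        S = self.sources_                         # d x k, fixed
        StS = S.T @ S
        StSp, StSm = positive_part(StS), negative_part(StS)
        StX = S.T @ V_new
        StXp, StXm = positive_part(StX), negative_part(StX)
        # strictly positive deterministic init: ridge least squares, clipped
        k = S.shape[1]
        H = np.linalg.solve(StS + 1e-8 * np.eye(k), StX)
        H = np.maximum(H, 0.0) + 0.2 * max(float(np.abs(H).mean()), _FLOOR)
        err = float(np.linalg.norm(V_new - S @ H, "fro"))
        for _ in range(max_iter):
            num = StXp + StSm @ H
            den = StXm + StSp @ H
            H = H * np.sqrt(num / np.maximum(den, _FLOOR))
            new_err = float(np.linalg.norm(V_new - S @ H, "fro"))
            change, err = err - new_err, new_err
            if abs(change) <= tol * max(err, _FLOOR):
                break
        return H.T

    # ------------------------------------------------------------------
    def rescale_sources(self) -> "ConvexNMF":
        """Normalize each source to unit Euclidean norm, compensating H.

        The product ``S H`` is unchanged; zero-norm (degenerate) sources
        are flagged in ``degenerate_sources_`` and left unscaled.
        Idempotent.
        """
        if not hasattr(self, "W_"):
            raise RuntimeError("fit must be called before rescale_sources")
        norms = np.linalg.norm(self.sources_, axis=0)
        degenerate = norms <= _FLOOR
        # exact idempotence: treat already-unit sources as such
        unit = np.abs(norms - 1.0) < 1e-12
        safe = np.where(degenerate | unit, 1.0, norms)
        self.sources_ = self.sources_ / safe
        self.W_ = self.W_ / safe
        self.H_ = self.H_ * safe[:, None]
        self.components_ = self.sources_.T
        self.source_norms_ = norms
        self.degenerate_sources_ = degenerate
        return self
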