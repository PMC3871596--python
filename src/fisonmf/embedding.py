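"""Distance-preserving embeddings of Fisher distance matrices.

Three multidimensional-scaling variants map points with given pairwise
(Fisher geodesic) distances into a q-dimensional Euclidean latent space:

* Sammon mapping — minimizes Sammon's stress
  ``E = (1 / sum d_ij) * sum (d_ij - delta_ij)^2 / d_ij`` by gradient
  descent with step halving;
* metric MDS — minimizes raw stress ``sum (d_ij - delta_ij)^2`` by SMACOF
  iterative majorization (each iterate provably does not increase stress);
* IMA — a *parametric* map: latent coordinates are ``V phi(i)`` where the
  basis functions ``phi_j(i) = exp(-d_F(x_i, c_j)^2 / (2 sigma^2))`` are
  Gaussian kernels of Fisher distances to training-point centers, and the
  weights V are fit by iterative majorization (a ridge-regularized
  least-squares subproblem per iteration).

All three initialize from classical (Torgerson) MDS, which makes the
optimization deterministic.  Out-of-sample points are embedded either by
applying the parametric map (IMA) or by minimizing the new point's own
stress contribution with the training coordinates frozen (Sammon/MDS).

Here ``d_ij`` denotes the given (target) dissimilarity and ``delta_ij`` the
Euclidean distance between the embedded coordinates.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.base import BaseEstimator

__all__ = ["SammonEmbedding", "SMACOFEmbedding", "IMAEmbedding"]


def classical_mds(D: np.ndarray, q: int) -> np.ndarray:
    """Torgerson's classical scaling: top-q eigenpairs of the Gram matrix."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:q]
    vals = np.clip(vals[order], 0.0, None)
    Y = vecs[:, order] * np.sqrt(vals)
    if Y.shape[1] < q:  # degenerate; pad
        Y = np.hstack([Y, np.zeros((n, q - Y.shape[1]))])
    return Y


def _check_D(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square distance matrix")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be symmetric")
    return 0.5 * (D + D.T)


def _merge_duplicates(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse zero-distance pairs; returns (reduced D, representative map).

    ``rep[i]`` is the index, in the reduced matrix, of point i's
    representative.
    """
    n = D.shape[0]
    rep = -np.ones(n, dtype=int)
    keep: list[int] = []
    for i in range(n):
        if rep[i] >= 0:
            continue
        rep_idx = len(keep)
        keep.append(i)
        dup = np.flatnonzero((D[i] <= 0) & (rep < 0))
        rep[dup] = rep_idx
        rep[i] = rep_idx
    idx = np.array(keep)
    return D[np.ix_(idx, idx)], rep


class _BaseMDS(BaseEstimator):
    """Shared plumbing: validation, duplicate merging, fitted attributes."""

    def __init__(self, n_components=2, max_iter=500, tol=1e-7):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, D: np.ndarray, y=None):
        D = _check_D(D)
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        self.dissimilarity_matrix_ = D
        Dr, rep = _merge_duplicates(D)
        Y, trace = self._optimize(Dr)
        self.embedding_ = Y[rep]
        self.stress_trace_ = trace
        self.stress_ = trace[-1]
        return self

    def fit_transform(self, D: np.ndarray, y=None) -> np.ndarray:
        return self.fit(D).embedding_

    # -- out-of-sample ---------------------------------------------------
    def _oos_point_stress(self, y, d_new, Y_train):
        raise NotImplementedError

    def transform(self, D_new: np.ndarray) -> np.ndarray:
        """Embed new points given their distances to the training points.

        Each new point's own stress contribution is minimized with the
        training coordinates frozen, starting from the coordinates of its
        nearest training neighbor.
        """
        if not hasattr(self, "embedding_"):
            raise RuntimeError("fit must be called before transform")
        D_new = np.atleast_2d(np.asarray(D_new, dtype=float))
        if D_new.shape[1] != self.embedding_.shape[0]:
            raise ValueError("D_new must have one column per training point")
        Y = self.embedding_
        out = np.empty((D_new.shape[0], self.n_components))
        for i, d in enumerate(D_new):
            y0 = Y[np.argmin(d)].copy()
            fun = lambda y: self._oos_point_stress(y, d, Y)  # noqa: E731
            res = minimize(fun, y0, method="L-BFGS-B", options={"maxiter": 200})
            out[i] = res.x if res.fun <= fun(y0) else y0
        return out


def _sammon_stress(D, Y):
    d = squareform(D, checks=False)
    delta = pdist(Y)
    c = d.sum()
    return float(np.sum((d - delta) ** 2 / np.maximum(d, 1e-300)) / c)


class SammonEmbedding(_BaseMDS):
    """Sammon mapping of a precomputed distance matrix.

    Gradient descent with step halving on Sammon's stress from a classical
    MDS start; ``stress_trace_`` is non-increasing by construction.
    """

    def _optimize(self, D):
        n = D.shape[0]
        q = self.n_components
        if n == 1:
            return np.zeros((1, q)), [0.0]
        Y = classical_mds(D, q)
        d = D.copy()
        c = squareform(d, checks=False).sum()
        stress = _sammon_stress(D, Y)
        trace = [stress]
        step = 0.3
        for _ in range(self.max_iter):
            delta = squareform(pdist(Y), checks=False)
            np.fill_diagonal(delta, 1.0)
            off = ~np.eye(n, dtype=bool)
            # dE/dY
            coef = np.zeros((n, n))
            coef[off] = (d[off] - delta[off]) / (d[off] * delta[off])
            grad = -(2.0 / c) * (
                coef.sum(axis=1)[:, None] * Y - coef @ Y
            )
            accepted = False
            for _try in range(40):
                Y_new = Y - step * grad
                s_new = _sammon_stress(D, Y_new)
                if s_new <= stress:
                    Y, stress = Y_new, s_new
                    step *= 1.1
                    accepted = True
                    break
                step *= 0.5
            if not accepted:
                break
            trace.append(stress)
            if len(trace) > 1 and trace[-2] - trace[-1] <= self.tol * max(trace[-2], 1e-300):
                break
        return Y, trace

    def _oos_point_stress(self, y, d_new, Y_train):
        delta = np.linalg.norm(Y_train - y, axis=1)
        d = np.maximum(d_new, 1e-300)
        return float(np.sum((d_new - delta) ** 2 / d))


class SMACOFEmbedding(_BaseMDS):
    """Metric MDS by SMACOF majorization on raw stress.

    Each Guttman-transform iterate cannot increase
    ``sum_{i<j} (d_ij - delta_ij)^2``; iteration stops at relative stress
    change below ``tol``.
    """

    @staticmethod
    def _raw_stress(D, Y):
        d = squareform(D, checks=False)
        return float(np.sum((d - pdist(Y)) ** 2))

    def _optimize(self, D):
        n = D.shape[0]
        q = self.n_components
        if n == 1:
            return np.zeros((1, q)), [0.0]
        Y = classical_mds(D, q)
        stress = self._raw_stress(D, Y)
        trace = [stress]
        for _ in range(self.max_iter):
            delta = squareform(pdist(Y), checks=False)
            np.fill_diagonal(delta, 1.0)
            B = -D / np.maximum(delta, 1e-300)
            np.fill_diagonal(B, 0.0)
            np.fill_diagonal(B, -B.sum(axis=1))
            Y_new = B @ Y / n                       # Guttman transform
            s_new = self._raw_stress(D, Y_new)
            if s_new > stress:                      # numerical safeguard
                break
            Y, prev, stress = Y_new, stress, s_new
            trace.append(stress)
            if prev - stress <= self.tol * max(prev, 1e-300):
                break
        return Y, trace

    def _oos_point_stress(self, y, d_new, Y_train):
        delta = np.linalg.norm(Y_train - y, axis=1)
        return float(np.sum((d_new - delta) ** 2))


class IMAEmbedding(_BaseMDS):
    """Parametric MDS: latent coordinates are linear in Gaussian basis
    functions of Fisher distances, fit by iterative majorization.

    Parameters
    ----------
    n_components : int
        Latent dimensionality q.
    sigma : float or "median"
        Kernel width in Fisher-distance units; "median" uses the median
        off-diagonal training distance.
    centers : array of int or "all"
        Training indices used as basis centers.
    ridge : float
        Tikhonov term in each least-squares subproblem.
    sammon_weighting : bool, default=False
        When True the stress carries Sammon-style 1/d_ij weights instead
        of the default unweighted (raw-stress) form.

    Attributes
    ----------
    weights_ : ndarray (m_centers, q)
        Basis-function coefficient matrix V.
    centers_ : ndarray of int
        Basis center indices into the training set.
    sigma_ : float
        Resolved kernel width.
    """

    def __init__(
        self,
        n_components=2,
        sigma="median",
        centers="all",
        ridge=1e-8,
        max_iter=500,
        tol=1e-7,
        sammon_weighting=False,
    ):
        super().__init__(n_components=n_components, max_iter=max_iter, tol=tol)
        self.sigma = sigma
        self.centers = centers
        self.ridge = ridge
        self.sammon_weighting = sammon_weighting

    def _basis(self, D_to_centers: np.ndarray) -> np.ndarray:
        return np.exp(-(D_to_centers**2) / (2.0 * self.sigma_**2))

    def fit(self, D: np.ndarray, y=None):
        D = _check_D(D)
        n = D.shape[0]
        q = self.n_components
        self.dissimilarity_matrix_ = D
        if self.centers == "all" or self.centers is None:
            self.centers_ = np.arange(n)
        else:
            self.centers_ = np.asarray(self.centers, dtype=int)
        if self.sigma == "median":
            off = squareform(D, checks=False)
            pos = off[off > 0]
            self.sigma_ = float(np.median(pos)) if pos.size else 1.0
        else:
            self.sigma_ = float(self.sigma)

        Phi = self._basis(D[:, self.centers_])              # (n, m)
        # optional Sammon-style 1/d weights; default unweighted raw stress
        Wt = np.ones((n, n))
        if self.sammon_weighting:
            with np.errstate(divide="ignore"):
                Wt = np.where(D > 0, 1.0 / np.maximum(D, 1e-300), 0.0)
        np.fill_diagonal(Wt, 0.0)

        def _stress(Y):
            delta = squareform(pdist(Y))
            return float(np.sum(Wt * (D - delta) ** 2) / 2.0)

        # majorization of the (weighted) stress with Y = Phi V constrained
        Y = classical_mds(D, q)
        ridge = self.ridge
        A = Phi.T @ Phi
        for _ in range(10):
            try:
                V = np.linalg.solve(A + ridge * np.eye(A.shape[0]), Phi.T @ Y)
                break
            except np.linalg.LinAlgError:
                ridge *= 100
                warnings.warn("singular IMA subproblem; ridge increased")
        Y = Phi @ V
        stress = _stress(Y)
        trace = [stress]
        Vn = np.diag(Wt.sum(axis=1)) - Wt                   # SMACOF V matrix
        M = Phi.T @ Vn @ Phi + ridge * np.eye(Phi.shape[1])
        for _ in range(self.max_iter):
            delta = squareform(pdist(Y), checks=False)
            np.fill_diagonal(delta, 1.0)
            B = -Wt * D / np.maximum(delta, 1e-300)
            np.fill_diagonal(B, 0.0)
            np.fill_diagonal(B, -B.sum(axis=1))
            rhs = Phi.T @ (B @ Y)
            try:
                V_new = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                ridge *= 100
                warnings.warn("singular IMA subproblem; ridge increased")
                M = Phi.T @ Vn @ Phi + ridge * np.eye(Phi.shape[1])
                continue
            Y_new = Phi @ V_new
            s_new = _stress(Y_new)
            if s_new > stress:                              # safeguard
                break
            V, Y, prev, stress = V_new, Y_new, stress, s_new
            trace.append(stress)
            if prev - stress <= self.tol * max(prev, 1e-300):
                break
        self.weights_ = V
        self.embedding_ = Y
        self.stress_trace_ = trace
        self.stress_ = trace[-1]
        return self

    def transform(self, D_new: np.ndarray) -> np.ndarray:
        """Apply the parametric map to new points (distances to training)."""
        if not hasattr(self, "weights_"):
            raise RuntimeError("fit must be called before transform")
        D_new = np.atleast_2d(np.asarray(D_new, dtype=float))
        if D_new.shape[1] != self.dissimilarity_matrix_.shape[0]:
            raise ValueError("D_new must have one column per training point")
        return self._basis(D_new[:, self.centers_]) @ self.weights_
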