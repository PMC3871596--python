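"""Shared fixtures: synthetic cohorts and duck-typed metric fields."""

import numpy as np
import pytest

from fisonmf import (
    MLPPosterior,
    generate_dataset,
    make_prototype_sources,
    split_dataset,
)


@pytest.fixture(scope="session")
def ste_prototypes():
    return make_prototype_sources(te_mode="STE")


@pytest.fixture(scope="session")
def lte_prototypes():
    return make_prototype_sources(te_mode="LTE")


@pytest.fixture(scope="session")
def separable_dataset(ste_prototypes):
    """Clean two-class cohort (low-grade vs metastasis archetypes)."""
    ds, gt = generate_dataset(
        ste_prototypes, {"A2": 22, "ME": 38}, noise_sd=0.005, overlap=0.0, seed=1
    )
    return ds, gt


@pytest.fixture(scope="session")
def trained_posterior(separable_dataset):
    """Posterior MLP fitted on the separable cohort's 2/3 split."""
    ds, _ = separable_dataset
    tr, ho = split_dataset(ds, seed=0)
    mlp = MLPPosterior(random_state=0, max_iter=300)
    mlp.fit(tr.X.T, tr.labels, ho.X.T, ho.labels)
    return mlp


class ConstantFieldModel:
    """Duck-typed posterior whose Fisher matrix is a fixed PSD matrix A.

    Probabilities are uniform and input-independent; the per-class
    log-posterior gradients are the scaled eigenvectors of A, so
    sum_c p_c g_c g_c^T = A everywhere (a flat metric field).
    """

    def __init__(self, A):
        A = np.asarray(A, dtype=float)
        vals, vecs = np.linalg.eigh(A)
        vals = np.clip(vals, 0.0, None)
        C = A.shape[0]
        self.p = np.full(C, 1.0 / C)
        self.G = (vecs * np.sqrt(vals / self.p)).T      # (C, d)

    def predict_proba(self, X):
        X = np.atleast_2d(X)
        return np.tile(self.p, (X.shape[0], 1))

    def log_proba_input_gradient(self, X):
        X = np.asarray(X)
        if X.ndim == 1:
            return self.G.copy()
        return np.tile(self.G[None], (X.shape[0], 1, 1))


@pytest.fixture
def constant_field_model():
    return ConstantFieldModel
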