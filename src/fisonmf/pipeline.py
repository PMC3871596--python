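"""End-to-end orchestration of the four source-extraction approaches.

``run_unsupervised`` fits Convex-NMF directly on the spectra.
``run_semisupervised`` runs the three-stage pipeline: a stratified 2/3-1/3
split trains the posterior MLP (assessed on the held-out third), the Fisher
geodesic distance matrix is computed over *all* training cases, the cases
are embedded (Sammon, SMACOF metric MDS, or the parametric IMA map), and
Convex-NMF factorizes the latent coordinates.  In both routes the sources
are rescaled to unit norm (the mixing matrix compensated), matched to
classes by correlation with class-mean spectra — semi-supervised sources
are first back-projected to the spectral domain through the unmixing
matrix — and every training case is labeled from its mixing-matrix argmax.
Independent test cases are labeled with the sources held fixed: new
geodesic distances -> out-of-sample embedding -> mixing-only multiplicative
updates.

A single master seed deterministically derives the per-stage seeds, so the
four approaches consume the identical training matrix and identical
K-means streams and differ only in the declared pipeline stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .convex_nmf import ConvexNMF
from .dataset import SpectrumDataset, class_mean_spectrum, split_dataset
from .embedding import IMAEmbedding, SammonEmbedding, SMACOFEmbedding
from .fisher import FisherGeodesicDistances
from .interpret import (
    EvalReport,
    SourceAssignment,
    assign_sources_to_classes,
    backproject_sources,
    evaluate,
    label_cases,
)
from .posterior import MLPPosterior

__all__ = [
    "ExperimentResult",
    "derive_seeds",
    "remap_superclass",
    "run_unsupervised",
    "run_semisupervised",
    "run_benchmark_suite",
]

_EMBEDDINGS = {
    "sammon": SammonEmbedding,
    "mds": SMACOFEmbedding,
    "ima": IMAEmbedding,
}


def derive_seeds(master: int | None, names: Sequence[str]) -> dict[str, int]:
    """Derive one independent 31-bit seed per named consumer."""
    ss = np.random.SeedSequence(0 if master is None else master)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def remap_superclass(
    dataset: SpectrumDataset, superclasses: Mapping[str, Sequence[str]]
) -> SpectrumDataset:
    """Merge classes into superclasses (e.g. AG = GL + ME) before analysis."""
    members: dict[str, str] = {}
    for sup, mem in superclasses.items():
        for m in mem:
            if m in members:
                raise ValueError(f"class {m!r} appears in two superclasses")
            members[m] = sup
    labels = [members.get(str(l), str(l)) for l in dataset.labels]
    return dataset.with_labels(labels)


@dataclass
class ExperimentResult:
    """Everything one approach produced on one problem."""

    approach: str
    n_sources: int
    assignment: SourceAssignment
    train_report: EvalReport
    train_predicted: np.ndarray
    test_report: EvalReport | None = None
    test_predicted: np.ndarray | None = None
    embedding_stress: float | None = None
    embedding_stress_trace: list[float] | None = None
    nmf_iterations: int = 0
    nmf_final_error: float = float("nan")
    nmf_converged: bool = False
    posterior_holdout_accuracy: float | None = None
    seeds: dict[str, int] = field(default_factory=dict)
    parametric_map: dict[str, Any] | None = None

    @property
    def mean_matched_correlation(self) -> float:
        """Mean over classes of the best source-class-mean correlation."""
        per_class = self.assignment.per_class_best_correlation()
        return float(np.mean(list(per_class.values())))


def _interpret_and_score(
    nmf: ConvexNMF,
    train: SpectrumDataset,
    spectral_sources: np.ndarray,
) -> tuple[SourceAssignment, Any, EvalReport]:
    means = {c: class_mean_spectrum(train, c) for c in train.classes}
    assignment = assign_sources_to_classes(spectral_sources, means)
    labeling = label_cases(nmf.H_, assignment)
    report = evaluate(labeling.predicted, train.labels)
    return assignment, labeling, report


def run_unsupervised(
    train: SpectrumDataset,
    n_sources: int = 2,
    seed: int | None = None,
    test: SpectrumDataset | None = None,
    tol: float = 1e-5,
    max_iter: int = 2000,
    restarts: int = 10,
) -> ExperimentResult:
    """Fully unsupervised route: Convex-NMF on the raw spectra."""
    if train.labels is None:
        raise ValueError("labeling evaluation requires a labeled training set")
    seeds = derive_seeds(seed, ["kmeans"])
    train = train.normalized()
    nmf = ConvexNMF(
        n_components=n_sources,
        tol=tol,
        max_iter=max_iter,
        restarts=restarts,
        random_state=seeds["kmeans"],
    ).fit(train.X.T)
    nmf.rescale_sources()
    assignment, labeling, report = _interpret_and_score(nmf, train, nmf.sources_)

    result = ExperimentResult(
        approach="convex",
        n_sources=n_sources,
        assignment=assignment,
        train_report=report,
        train_predicted=labeling.predicted,
        nmf_iterations=len(nmf.objective_trace_) - 1,
        nmf_final_error=nmf.objective_trace_[-1],
        nmf_converged=nmf.converged_,
        seeds=seeds,
    )
    if test is not None:
        test = test.normalized()
        H_new = nmf.transform(test.X.T).T
        test_labeling = label_cases(H_new, assignment)
        result.test_predicted = test_labeling.predicted
        if test.labels is not None:
            result.test_report = evaluate(test_labeling.predicted, test.labels)
    return result


def run_semisupervised(
    train: SpectrumDataset,
    method: str = "ima",
    n_sources: int = 2,
    seed: int | None = None,
    test: SpectrumDataset | None = None,
    latent_dim: int | None = None,
    split_fraction: float = 2.0 / 3.0,
    hidden_units: int = 8,
    weight_decay: float = 1e-3,
    mlp_max_iter: int = 500,
    n_neighbors: int = 10,
    subdivisions: int = 4,
    tol: float = 1e-5,
    max_iter: int = 2000,
    restarts: int = 10,
) -> ExperimentResult:
    """Semi-supervised route: Fisher metric -> embedding -> Convex-NMF."""
    if method not in _EMBEDDINGS:
        raise ValueError(f"method must be one of {sorted(_EMBEDDINGS)}")
    if train.labels is None:
        raise ValueError("semi-supervised extraction requires labels")
    seeds = derive_seeds(seed, ["kmeans", "split", "mlp"])
    train = train.normalized()

    # stage (i): posterior model on a stratified 2/3 split
    tr, ho = split_dataset(train, split_fraction, seeds["split"])
    mlp = MLPPosterior(
        hidden_units=hidden_units,
        alpha=weight_decay,
        max_iter=mlp_max_iter,
        random_state=seeds["mlp"],
    ).fit(tr.X.T, tr.labels, ho.X.T, ho.labels)

    # Fisher geodesic distances over all training cases
    geo = FisherGeodesicDistances(
        mlp, n_neighbors=n_neighbors, subdivisions=subdivisions
    ).fit(train.X.T)

    # stage (ii): embed into the Euclidean latent space
    q = latent_dim if latent_dim is not None else max(2, len(train.classes))
    emb = _EMBEDDINGS[method](n_components=q).fit(geo.distances_)

    # stage (iii): Convex-NMF on the latent coordinates.  The embedding
    # fixes coordinates only up to rigid motion, while Convex-NMF is
    # translation-sensitive: a mean-centered configuration straddles the
    # origin and its conic constraints become vacuous.  Anchor the gauge by
    # translating the cloud into the positive orthant, offset from the
    # origin by its own range, so the cone constraints stay informative.
    Y = emb.embedding_
    span = float(np.max(Y.max(axis=0) - Y.min(axis=0)))
    anchor = Y.min(axis=0) - max(span, 1e-12)
    nmf = ConvexNMF(
        n_components=n_sources,
        tol=tol,
        max_iter=max_iter,
        restarts=restarts,
        random_state=seeds["kmeans"],
    ).fit(Y - anchor)
    nmf.rescale_sources()

    spectral = backproject_sources(nmf.W_, train.X)
    assignment, labeling, report = _interpret_and_score(nmf, train, spectral)

    result = ExperimentResult(
        approach=method,
        n_sources=n_sources,
        assignment=assignment,
        train_report=report,
        train_predicted=labeling.predicted,
        embedding_stress=emb.stress_,
        embedding_stress_trace=list(emb.stress_trace_),
        nmf_iterations=len(nmf.objective_trace_) - 1,
        nmf_final_error=nmf.objective_trace_[-1],
        nmf_converged=nmf.converged_,
        posterior_holdout_accuracy=mlp.validation_accuracy_,
        seeds=seeds,
    )
    if method == "ima":
        result.parametric_map = {
            "weights": emb.weights_,
            "centers": emb.centers_,
            "sigma": emb.sigma_,
        }
    if test is not None:
        test = test.normalized()
        D_new = geo.transform(test.X.T)
        Y_new = emb.transform(D_new) - anchor
        H_new = nmf.transform(Y_new).T
        test_labeling = label_cases(H_new, assignment)
        result.test_predicted = test_labeling.predicted
        if test.labels is not None:
            result.test_report = evaluate(test_labeling.predicted, test.labels)
    return result


def run_experiment(config: Mapping[str, Any]) -> ExperimentResult:
    """Dispatch one config dict to the matching route.

    Recognized keys: ``train`` (SpectrumDataset, required), ``method``
    (``convex`` or an embedding name), ``n_sources``, ``seed``, ``test``,
    plus any keyword accepted by the route functions.
    """
    cfg = dict(config)
    cfg.pop("name", None)
    method = cfg.pop("method", "convex")
    if method == "convex":
        allowed = {"train", "n_sources", "seed", "test", "tol", "max_iter", "restarts"}
        return run_unsupervised(**{k: v for k, v in cfg.items() if k in allowed})
    return run_semisupervised(method=method, **cfg)


def run_benchmark_suite(configs: Sequence[Mapping[str, Any]]) -> pd.DataFrame:
    """Run a list of experiment configs into a table-shaped report.

    One row per (config, metric) with cells formatted like
    ``"88.0% (95/108)"``; a failing config is reported as failed and the
    suite continues.
    """
    rows: list[dict[str, Any]] = []
    for i, cfg in enumerate(configs):
        name = cfg.get("name", f"experiment{i + 1}")
        method = cfg.get("method", "convex")
        try:
            res = run_experiment(cfg)
        except Exception as exc:  # noqa: BLE001 - suite keeps going
            rows.append(
                {"problem": name, "method": method, "metric": "error",
                 "value": f"FAILED: {exc}"}
            )
            continue
        for scope, report in (("train", res.train_report), ("test", res.test_report)):
            if report is None:
                continue
            for metric, cell in report.formatted().items():
                rows.append(
                    {"problem": name, "method": method,
                     "metric": f"{scope} {metric}", "value": cell}
                )
        for cls, r in res.assignment.per_class_best_correlation().items():
            rows.append(
                {"problem": name, "method": method,
                 "metric": f"correlation {cls}", "value": f"{r:.3f}"}
            )
    return pd.DataFrame(rows, columns=["problem", "method", "metric", "value"])
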