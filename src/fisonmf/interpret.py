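"""From a fitted factorization to tumor-type sources, labels and scores.

Sources fitted in a latent space are back-projected to the spectral domain
by applying the non-negative unmixing matrix W to the original spectra
(``X_original @ W``).  Each spectral source is then assigned to the tumor
class whose mean spectrum it correlates with best, under the constraint
that every class receives at least one source when there are at least as
many sources as classes; with at most a handful of sources the optimal
assignment is found by exhaustive enumeration.  Cases are labeled by the
class of the source winning the argmax over their mixing-matrix column, and
labelings are scored by total accuracy, per-class accuracy and the balanced
error rate (BER) — the mean of per-class error rates, robust to class
imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .dataset import ul2_normalize

__all__ = [
    "SourceAssignment",
    "LabelingResult",
    "EvalReport",
    "backproject_sources",
    "assign_sources_to_classes",
    "label_cases",
    "evaluate",
]


def backproject_sources(W: np.ndarray, X_original: np.ndarray) -> np.ndarray:
    """Project unmixing weights onto the original spectra: ``X W``.

    ``X_original`` is d x n (frequencies x cases); ``W`` is n x k.  Columns
    of the result are UL2-normalized so they can be displayed on the ppm
    axis and correlated with class-mean spectra.
    """
    W = np.asarray(W, dtype=float)
    X_original = np.asarray(X_original, dtype=float)
    if X_original.shape[1] != W.shape[0]:
        raise ValueError(
            f"X has {X_original.shape[1]} cases but W has {W.shape[0]} rows"
        )
    return ul2_normalize(X_original @ W)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(np.dot(a, b) / (na * nb))


@dataclass
class SourceAssignment:
    """Map from extracted sources to tumor classes, with the evidence."""

    spectral_sources: np.ndarray              # d x k
    class_of_source: dict[int, str]
    correlations: np.ndarray                  # k x C Pearson matrix
    class_names: list[str]
    flipped_sources: list[int] = field(default_factory=list)
    distance_assigned: list[int] = field(default_factory=list)

    @property
    def matched_correlations(self) -> dict[int, float]:
        """Correlation of each source with its assigned class's mean."""
        col = {c: j for j, c in enumerate(self.class_names)}
        return {
            s: float(self.correlations[s, col[c]])
            for s, c in self.class_of_source.items()
        }

    def per_class_best_correlation(self) -> dict[str, float]:
        """For each class, the best matched correlation among its sources."""
        out: dict[str, float] = {}
        for s, r in self.matched_correlations.items():
            c = self.class_of_source[s]
            out[c] = max(out.get(c, -np.inf), r)
        return out


def assign_sources_to_classes(
    spectral_sources: np.ndarray,
    class_means: dict[str, np.ndarray],
    allow_sign_flip: bool = True,
) -> SourceAssignment:
    """Assign each source to a class by Pearson correlation with class means.

    The assignment maximizes the total correlation subject to every class
    receiving at least one source whenever ``k >= C``; surplus sources go
    to their best class.  With ``k <= 6`` (always the case here) the
    optimum is found by exhaustive enumeration.  A source anti-correlated
    with every class mean has its sign flipped first (latent-space sign
    indeterminacy); a zero-variance source is assigned by Euclidean
    distance and flagged.
    """
    S = np.asarray(spectral_sources, dtype=float).copy()
    class_names = sorted(class_means)
    C = len(class_names)
    k = S.shape[1]
    if C < 2:
        raise ValueError("need at least 2 classes")
    if k < 1:
        raise ValueError("need at least 1 source")
    if k > 6:
        raise ValueError("exhaustive matching supports at most 6 sources")
    means = np.column_stack([ul2_normalize(class_means[c]) for c in class_names])

    corr = np.empty((k, C))
    flipped: list[int] = []
    dist_assigned: list[int] = []
    for s in range(k):
        src = ul2_normalize(S[:, s]) if np.linalg.norm(S[:, s]) > 0 else S[:, s]
        row = np.array([_pearson(src, means[:, j]) for j in range(C)])
        if np.all(np.isnan(row)):
            # constant source: fall back to Euclidean proximity
            d = np.linalg.norm(means - S[:, [s]], axis=0)
            row = 1.0 - d / max(d.max(), 1e-300)
            dist_assigned.append(s)
            warnings.warn(f"source {s} has zero variance; assigned by distance")
        elif allow_sign_flip and np.nanmax(row) < 0:
            S[:, s] = -S[:, s]
            row = -row
            flipped.append(s)
        corr[s] = row

    best: tuple[float, tuple[int, ...]] | None = None
    for assign in product(range(C), repeat=k):
        if k >= C and len(set(assign)) < C:
            continue  # every class must receive a source
        total = sum(corr[s, a] for s, a in enumerate(assign))
        if best is None or total > best[0]:
            best = (total, assign)
    assert best is not None
    class_of_source = {s: class_names[a] for s, a in enumerate(best[1])}
    return SourceAssignment(
        spectral_sources=S,
        class_of_source=class_of_source,
        correlations=corr,
        class_names=class_names,
        flipped_sources=flipped,
        distance_assigned=dist_assigned,
    )


@dataclass
class LabelingResult:
    predicted: np.ndarray
    H_used: np.ndarray
    source_argmax: np.ndarray


def label_cases(
    H: np.ndarray,
    assignment: SourceAssignment,
    fallback_class: str | None = None,
) -> LabelingResult:
    """Label each case by the source with the highest mixing weight.

    ``H`` is k x n (post source-rescaling).  Ties break toward the lowest
    source index; an all-zero column is labeled with ``fallback_class``
    (or the first class name) and flagged with a warning.
    """
    H = np.asarray(H, dtype=float)
    k, n = H.shape
    if set(assignment.class_of_source) != set(range(k)):
        raise ValueError("assignment must cover every source row of H")
    winner = np.argmax(H, axis=0)              # argmax breaks ties low
    predicted = np.array(
        [assignment.class_of_source[int(w)] for w in winner], dtype=object
    )
    dead = np.flatnonzero(np.all(H == 0, axis=0))
    if dead.size:
        fb = fallback_class or assignment.class_names[0]
        predicted[dead] = fb
        warnings.warn(f"{dead.size} all-zero mixing column(s) labeled {fb!r}")
    return LabelingResult(predicted=predicted, H_used=H, source_argmax=winner)


@dataclass
class EvalReport:
    """Accuracy summary of a labeling against ground truth."""

    total_accuracy: float                      # percent
    per_class_accuracy: dict[str, float]       # percent per class
    correct_counts: dict[str, tuple[int, int]]
    ber: float

    def formatted(self) -> dict[str, str]:
        """Cells in the ``"88.0% (95/108)"`` style."""
        out = {
            "Total": format_count_cell(
                sum(c for c, _ in self.correct_counts.values()),
                sum(t for _, t in self.correct_counts.values()),
            )
        }
        for cls, (c, t) in self.correct_counts.items():
            out[cls] = format_count_cell(c, t)
        out["BER"] = f"{self.ber:.3f}"
        return out


def format_count_cell(correct: int, total: int) -> str:
    return f"{100.0 * correct / total:.1f}% ({correct}/{total})"


def evaluate(predicted: np.ndarray, truth: np.ndarray) -> EvalReport:
    """Score predicted labels: per-class counts, total accuracy, BER.

    BER is the mean over classes of the per-class error rate; duplicating
    every member of one class leaves it unchanged.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must have equal length")
    classes = sorted(set(truth.tolist()))
    unknown = set(predicted.tolist()) - set(classes)
    if unknown:
        raise ValueError(f"predicted label(s) {unknown} absent from truth classes")
    counts: dict[str, tuple[int, int]] = {}
    accs: dict[str, float] = {}
    for cls in classes:
        mask = truth == cls
        total = int(mask.sum())
        correct = int((predicted[mask] == cls).sum())
        counts[cls] = (correct, total)
        accs[cls] = 100.0 * correct / total
    total_acc = 100.0 * sum(c for c, _ in counts.values()) / truth.size
    ber = float(np.mean([1.0 - accs[c] / 100.0 for c in classes]))
    return EvalReport(
        total_accuracy=total_acc,
        per_class_accuracy=accs,
        correct_counts=counts,
        ber=ber,
    )
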