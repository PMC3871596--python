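"""Source-to-class assignment, labeling and evaluation arithmetic."""

from itertools import product

import numpy as np
import pytest

from fisonmf import (
    assign_sources_to_classes,
    backproject_sources,
    evaluate,
    label_cases,
)
from fisonmf.dataset import ul2_normalize
from fisonmf.interpret import format_count_cell


def _predictions_from_counts(counts):
    """Build (predicted, truth) label arrays realizing per-class counts."""
    pred, truth = [], []
    classes = sorted(counts)
    for cls, (correct, total) in counts.items():
        wrong = [c for c in classes if c != cls][0]
        truth += [cls] * total
        pred += [cls] * correct + [wrong] * (total - correct)
    return np.array(pred, dtype=object), np.array(truth, dtype=object)


class TestBackproject:
    def test_one_hot_weights_select_a_normalized_spectrum(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 5))
        W = np.zeros((5, 2))
        W[2, 0] = 3.0                        # scaled one-hot
        W[4, 1] = 1.0
        S = backproject_sources(W, X)
        assert np.allclose(S[:, 0], ul2_normalize(X[:, 2]))
        assert np.allclose(S[:, 1], ul2_normalize(X[:, 4]))

    def test_case_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            backproject_sources(np.ones((4, 2)), np.ones((6, 5)))


class TestAssignment:
    def test_sources_equal_to_class_means_assign_identically(self):
        rng = np.random.default_rng(1)
        means = {"A2": rng.normal(size=10), "GL": rng.normal(size=10)}
        S = np.column_stack([means["A2"], means["GL"]])
        asg = assign_sources_to_classes(S, means)
        assert asg.class_of_source == {0: "A2", 1: "GL"}
        assert all(r == pytest.approx(1.0) for r in asg.matched_correlations.values())

    def test_three_sources_two_classes_pigeonhole(self):
        rng = np.random.default_rng(2)
        means = {"A2": rng.normal(size=8), "AG": rng.normal(size=8)}
        S = np.column_stack(
            [means["A2"], means["AG"], 0.7 * means["AG"] + 0.3 * rng.normal(size=8)]
        )
        asg = assign_sources_to_classes(S, means)
        counts = {c: list(asg.class_of_source.values()).count(c) for c in means}
        assert sorted(counts.values()) == [1, 2]

    def test_matches_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for k in (2, 3, 4):
            means = {c: rng.normal(size=12) for c in ("A2", "GL", "ME")[:2]}
            S = rng.normal(size=(12, k))
            asg = assign_sources_to_classes(S, means, allow_sign_flip=False)
            names = sorted(means)
            # independent oracle: enumerate all class-covering assignments
            corr = np.array(
                [
                    [np.corrcoef(S[:, s], means[c])[0, 1] for c in names]
                    for s in range(k)
                ]
            )
            best, best_assign = -np.inf, None
            for assign in product(range(len(names)), repeat=k):
                if k >= len(names) and len(set(assign)) < len(names):
                    continue
                total = sum(corr[s, a] for s, a in enumerate(assign))
                if total > best:
                    best, best_assign = total, assign
            expected = {s: names[a] for s, a in enumerate(best_assign)}
            assert asg.class_of_source == expected

    def test_anticorrelated_source_gets_sign_flipped(self):
        rng = np.random.default_rng(4)
        means = {"A2": rng.normal(size=10), "GL": rng.normal(size=10)}
        S = np.column_stack([-means["A2"], means["GL"]])
        asg = assign_sources_to_classes(S, means)
        assert asg.flipped_sources == [0]
        assert asg.matched_correlations[0] == pytest.approx(1.0)

    def test_constant_source_assigned_by_distance_and_flagged(self):
        rng = np.random.default_rng(5)
        means = {"A2": rng.normal(size=10), "GL": rng.normal(size=10)}
        S = np.column_stack([np.full(10, 0.3), means["GL"]])
        with pytest.warns(UserWarning, match="zero variance"):
            asg = assign_sources_to_classes(S, means)
        assert asg.distance_assigned == [0]


class TestLabeling:
    def test_one_hot_column_takes_source_class(self):
        rng = np.random.default_rng(6)
        means = {"A2": rng.normal(size=6), "AG": rng.normal(size=6)}
        S = np.column_stack([means["A2"], means["AG"], means["AG"] * 0.9])
        asg = assign_sources_to_classes(S, means)
        H = np.zeros((3, 4))
        H[0, 0] = H[1, 1] = H[2, 2] = H[2, 3] = 1.0
        res = label_cases(H, asg)
        assert list(res.predicted) == [
            asg.class_of_source[0],
            asg.class_of_source[1],
            asg.class_of_source[2],
            asg.class_of_source[2],
        ]

    def test_matches_argmax_oracle_on_random_mixing(self):
        rng = np.random.default_rng(7)
        means = {"A2": rng.normal(size=6), "GL": rng.normal(size=6)}
        S = np.column_stack([means["A2"], means["GL"]])
        asg = assign_sources_to_classes(S, means)
        H = rng.uniform(size=(2, 30))
        res = label_cases(H, asg)
        expected = [asg.class_of_source[int(i)] for i in np.argmax(H, axis=0)]
        assert list(res.predicted) == expected

    def test_all_zero_column_gets_fallback_and_warning(self):
        rng = np.random.default_rng(8)
        means = {"A2": rng.normal(size=6), "GL": rng.normal(size=6)}
        asg = assign_sources_to_classes(
            np.column_stack([means["A2"], means["GL"]]), means
        )
        H = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            res = label_cases(H, asg, fallback_class="GL")
        assert res.predicted[1] == "GL"


class TestEvaluate:
    @pytest.mark.parametrize(
        "counts,total,ber",
        [
            # per-class (correct, total) pairs from two-class cohorts
            ({"A2": (22, 22), "GL": (73, 86)}, 88.0, 0.076),
            ({"GL": (61, 86), "ME": (33, 38)}, 75.8, 0.211),
        ],
    )
    def test_worked_accuracy_and_ber_examples(self, counts, total, ber):
        pred, truth = _predictions_from_counts(counts)
        rep = evaluate(pred, truth)
        assert round(rep.total_accuracy, 1) == total
        assert round(rep.ber, 3) == ber

    def test_perfect_prediction(self):
        truth = np.array(["A2"] * 5 + ["GL"] * 9, dtype=object)
        rep = evaluate(truth.copy(), truth)
        assert rep.total_accuracy == 100.0
        assert rep.ber == 0.0

    def test_ber_invariant_to_class_duplication(self):
        counts = {"A2": (18, 22), "GL": (70, 86)}
        pred, truth = _predictions_from_counts(counts)
        rep1 = evaluate(pred, truth)
        dup_mask = truth == "GL"
        pred2 = np.concatenate([pred, pred[dup_mask]])
        truth2 = np.concatenate([truth, truth[dup_mask]])
        rep2 = evaluate(pred2, truth2)
        assert rep2.ber == pytest.approx(rep1.ber, abs=1e-12)
        assert rep2.total_accuracy != pytest.approx(rep1.total_accuracy)

    def test_unknown_predicted_label_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array(["XX"], dtype=object), np.array(["A2"], dtype=object))

    def test_cell_formatting(self):
        assert format_count_cell(95, 108) == "88.0% (95/108)"
        assert format_count_cell(13, 86) == "15.1% (13/86)"
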