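"""Agreement metrics: kappa against brute force, recall, consensus rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tmagleason.evaluation import (
    SPOT_SCORE_ORDER,
    common_subset,
    confusion_matrix,
    consensus_precision,
    macro_recall,
    quadratic_kappa,
)


def brute_force_kappa(O):
    """Direct, loop-based evaluation of the quadratic weighted kappa."""
    O = np.asarray(O, dtype=float)
    N = O.shape[0]
    total = O.sum()
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    num = den = 0.0
    for i in range(N):
        for j in range(N):
            w = (i - j) ** 2 / (N - 1) ** 2
            num += w * O[i, j]
            den += w * row[i] * col[j] / total
    return 1.0 - num / den


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        O, norm = confusion_matrix(["G3", "G4"], ["G3", "G4"],
                                   ["Benign", "G3", "G4", "G5"])
        assert O[1, 1] == 1 and O[2, 2] == 1 and O.sum() == 2

    def test_counting_example(self):
        O, norm = confusion_matrix(["G3", "G3", "G4"], ["G3", "G4", "G4"],
                                   ["G3", "G4"])
        assert O.tolist() == [[1, 1], [0, 1]]
        assert np.allclose(norm, [[0.5, 0.5], [0, 1]])

    def test_total_conserved(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 4, 50)
        b = rng.integers(0, 4, 50)
        O, _ = confusion_matrix(a, b, range(4))
        assert O.sum() == 50

    def test_unknown_label_named_in_error(self):
        with pytest.raises(ValueError, match="G9"):
            confusion_matrix(["G9"], ["G3"], ["G3", "G4"])


class TestQuadraticKappa:
    def test_diagonal_matrix_gives_one(self):
        assert quadratic_kappa(np.diag([3, 1, 4, 1])) == pytest.approx(1.0)

    def test_independence_gives_zero(self):
        row = np.array([10, 20, 5, 15], dtype=float)
        col = np.array([8, 12, 18, 12], dtype=float)
        O = np.outer(row, col) / col.sum()
        assert quadratic_kappa(O) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [4, 6])
    def test_matches_brute_force_on_random_matrices(self, n):
        rng = np.random.default_rng(42)
        for _ in range(200):
            O = rng.integers(0, 30, size=(n, n))
            if O.sum() == 0 or quadratic_kappa_denominator_zero(O):
                continue
            assert quadratic_kappa(O) == pytest.approx(
                brute_force_kappa(O), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(7)
        a = rng.integers(0, 5, 200)
        b = np.clip(a + rng.integers(-1, 2, 200), 0, 4)
        O, _ = confusion_matrix(a, b, range(5))
        assert quadratic_kappa(O) == pytest.approx(
            cohen_kappa_score(a, b, weights="quadratic"), abs=1e-10)

    @given(arrays(np.int64, (4, 4), elements=st.integers(0, 20)))
    @settings(max_examples=60, deadline=None)
    def test_symmetry_and_scaling_invariance(self, O):
        if O.sum() == 0 or quadratic_kappa_denominator_zero(O):
            return
        k = quadratic_kappa(O)
        assert quadratic_kappa(O.T) == pytest.approx(k, abs=1e-10)
        assert quadratic_kappa(3 * O) == pytest.approx(k, abs=1e-10)
        assert k <= 1.0 + 1e-12

    def test_degenerate_marginals_rejected(self):
        O = np.zeros((4, 4), dtype=int)
        O[2, 2] = 10                     # all mass in one cell
        with pytest.raises(ValueError, match="degenerate"):
            quadratic_kappa(O)


def quadratic_kappa_denominator_zero(O):
    O = np.asarray(O, dtype=float)
    N = O.shape[0]
    i = np.arange(N)
    w = (i[:, None] - i[None, :]) ** 2
    E = np.outer(O.sum(1), O.sum(0))
    return (w * E).sum() == 0


class TestMacroRecall:
    def test_diagonal_is_one(self):
        assert macro_recall(np.diag([5, 2, 7])) == 1.0

    def test_hand_example(self):
        O = np.array([[9, 1], [5, 5]])
        assert macro_recall(O) == pytest.approx(0.7)

    def test_absent_class_excluded(self):
        O = np.array([[8, 2, 0], [1, 9, 0], [0, 0, 0]])
        assert macro_recall(O) == pytest.approx((0.8 + 0.9) / 2)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            macro_recall(np.zeros((3, 3)))


class TestCommonSubset:
    def test_disjoint_raters_warn_empty(self):
        with pytest.warns(UserWarning, match="no annotated"):
            df = common_subset({"a": 1}, {"b": 2}, {})
        assert len(df) == 0

    def test_identical_keys_preserved(self):
        df = common_subset({"a": 1, "b": 2}, {"a": 1, "b": 3},
                           {"a": 9, "b": 8})
        assert list(df["id"]) == ["a", "b"]

    def test_partial_overlap(self):
        a = {k: 1 for k in "abcde"}
        b = {k: 2 for k in "cdef"}
        df = common_subset(a, b, {})
        assert list(df["id"]) == ["c", "d", "e"]

    def test_null_annotations_excluded(self):
        df = common_subset({"a": 1, "b": None}, {"a": 2, "b": 2}, {})
        assert list(df["id"]) == ["a"]


class TestConsensusPrecision:
    def test_full_agreement(self):
        p = consensus_precision(["G3", "G4"], ["G3", "G4"], ["G3", "G4"])
        assert p == {"G3": 1.0, "G4": 1.0}

    def test_one_rater_suffices(self):
        p = consensus_precision(["G5"], ["G4"], ["G5"])
        assert p["G5"] == 1.0

    def test_neither_rater_matches(self):
        p = consensus_precision(["Benign"], ["G3"], ["G4"])
        assert p["Benign"] == 0.0

    def test_never_predicted_class_absent(self):
        p = consensus_precision(["G3"], ["G3"], ["G3"])
        assert "G5" not in p


def test_spot_level_pipeline_perfect_predictions_give_kappa_one():
    """score ordering Benign < 6 < ... < 10 through the kappa machinery."""
    scores = [0, 6, 6, 7, 8, 9, 10, 7]
    O, _ = confusion_matrix(scores, scores, SPOT_SCORE_ORDER)
    assert quadratic_kappa(O) == pytest.approx(1.0)
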