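"""Agreement metrics between annotators (model vs rater, rater vs rater).

The headline statistic is the quadratic weighted Cohen kappa for ordered
categories,

    kappa = 1 - sum_ij w_ij O_ij / sum_ij w_ij E_ij,
    w_ij  = (i - j)^2 / (N - 1)^2,

where O is the observed contingency matrix, and E_ij the expected counts
under independent raters (outer product of the marginals divided by the
grand total).  Macro-average recall complements it as an imbalance-proof
accuracy measure.  Patch-level comparisons use the ordered classes
(Benign, G3, G4, G5); spot-level comparisons use composite scores
ordered as Benign < 6 < 7 < ... < 10.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "confusion_matrix",
    "quadratic_kappa",
    "macro_recall",
    "common_subset",
    "consensus_precision",
    "SPOT_SCORE_ORDER",
]

#: spot-level ordinal embedding: benign is rank-adjacent below score 6
SPOT_SCORE_ORDER = (0, 6, 7, 8, 9, 10)


def confusion_matrix(labels_a, labels_b, ordered_classes):
    """Counts O_ij and the row-normalized (recall) matrix.

    Rows index ``labels_a`` (ground truth), columns ``labels_b``.
    Unknown labels raise; rows with no observations stay zero in the
    normalized matrix.
    """
    classes = list(ordered_classes)
    index = {c: i for i, c in enumerate(classes)}
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError("label sequences differ in length")
    O = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for x, y in zip(a, b):
        if x not in index:
            raise ValueError(f"unknown label {x!r} in first sequence")
        if y not in index:
            raise ValueError(f"unknown label {y!r} in second sequence")
        O[index[x], index[y]] += 1
    rowsum = O.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(rowsum > 0, O / rowsum, 0.0)
    return O, norm


def quadratic_kappa(O: np.ndarray) -> float:
    """Quadratic weighted Cohen kappa of a contingency counts matrix."""
    O = np.asarray(O, dtype=np.float64)
    N = O.shape[0]
    if O.shape != (N, N) or N < 2:
        raise ValueError("O must be a square matrix with N >= 2")
    if (O < 0).any():
        raise ValueError("O must be nonnegative")
    total = O.sum()
    if total <= 0:
        raise ValueError("O has no observations")
    i = np.arange(N)
    w = (i[:, None] - i[None, :]) ** 2 / (N - 1) ** 2
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / total
    denom = (w * E).sum()
    if denom <= 0:
        raise ValueError("degenerate marginals: expected disagreement is zero")
    return float(1.0 - (w * O).sum() / denom)


def macro_recall(O: np.ndarray) -> float:
    """Unweighted mean of per-class recall O_ii / row_i.

    Classes absent from the truth (empty rows) are excluded from the
    average.
    """
    O = np.asarray(O, dtype=np.float64)
    rows = O.sum(axis=1)
    present = rows > 0
    if not present.any():
        raise ValueError("confusion matrix has no observations")
    recalls = np.diag(O)[present] / rows[present]
    return float(recalls.mean())


def common_subset(annotations_a: dict, annotations_b: dict,
                  predictions: dict) -> pd.DataFrame:
    """Align on the ids annotated by both raters.

    Returns a DataFrame (id, rater_a, rater_b, prediction) restricted to
    ids with non-null annotations from both raters; an empty overlap is
    allowed but warned about.
    """
    ids = sorted(k for k in annotations_a
                 if annotations_a.get(k) is not None
                 and annotations_b.get(k) is not None)
    if not ids:
        warnings.warn("raters share no annotated items")
    return pd.DataFrame({
        "id": ids,
        "rater_a": [annotations_a[k] for k in ids],
        "rater_b": [annotations_b[k] for k in ids],
        "prediction": [predictions.get(k) for k in ids],
    })


def consensus_precision(predictions, rater_a, rater_b) -> dict:
    """Per-class precision against the union of two raters.

    A prediction counts as correct when it coincides with at least one
    rater's annotation.  Classes never predicted are absent from the
    result.
    """
    predictions = list(predictions)
    rater_a = list(rater_a)
    rater_b = list(rater_b)
    if not len(predictions) == len(rater_a) == len(rater_b):
        raise ValueError("inputs must be aligned sequences of equal length")
    out: dict = {}
    for cls in sorted(set(predictions), key=str):
        sel = [i for i, p in enumerate(predictions) if p == cls]
        hits = sum(1 for i in sel
                   if predictions[i] == rater_a[i] or predictions[i] == rater_b[i])
        out[cls] = hits / len(sel)
    return out
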