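"""Composite Gleason score assignment from pixel probability maps.

Given per-pixel class probabilities o_{i,j}^k over (Benign, G3, G4, G5),
each class first receives a weighted score

    w^k = sum_{i,j} o_{i,j}^k / sum_{i,j,k} o_{i,j}^k,

with the sums running over tissue pixels, and then a final score

    w_final^k = 1{w^k > c} * w^k,     c = 0.25 by default,

so that only classes covering more than a quarter of the probability
mass survive.  The primary Gleason pattern is the cancer pattern
(3/4/5) with the largest final score, the secondary the second largest
(defaulting to the primary when it is the only one), and the composite
score is their sum; a spot with no surviving cancer pattern is benign.

The threshold comparison is strict.  With four classes a perfectly
uniform map (all weights exactly 0.25) would zero every class; the
default tie rule keeps the largest-weight class in that degenerate case
so an assignment always exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ProbabilityMap

__all__ = ["ScoringConfig", "GleasonAssignment", "class_weights",
           "assign_score", "score_cohort"]

#: cancer patterns by channel index (channel 0 is Benign)
_PATTERN_OF_CHANNEL = {1: 3, 2: 4, 3: 5}


@dataclass(frozen=True)
class ScoringConfig:
    threshold: float = 0.25
    #: "argmax" keeps the largest-weight class when the strict threshold
    #: zeroes all four classes; "strict" reports benign in that case
    tie_rule: str = "argmax"

    def __post_init__(self):
        if not 0 <= self.threshold < 1:
            raise ValueError("threshold must be in [0, 1)")
        if self.tie_rule not in ("argmax", "strict"):
            raise ValueError(f"unknown tie_rule {self.tie_rule!r}")


@dataclass
class GleasonAssignment:
    class_weights: np.ndarray       # w^k, 4-vector on the simplex
    final_scores: np.ndarray        # w_final^k
    primary: int | None             # Gleason pattern 3/4/5 or None
    secondary: int | None
    composite: int                  # 6..10, or 0 for benign

    @property
    def is_benign(self) -> bool:
        return self.composite == 0

    @property
    def label(self) -> str:
        return "Benign" if self.is_benign else str(self.composite)


def class_weights(pmap: ProbabilityMap) -> np.ndarray:
    """Weighted score w^k of each class over the map's tissue pixels."""
    tissue = pmap.tissue_mask
    if not tissue.any():
        raise ValueError("probability map has no tissue pixels")
    sums = pmap.probs[tissue].sum(axis=0, dtype=np.float64)
    total = sums.sum()
    if total <= 0:
        raise ValueError("probability map is all zero on tissue")
    return sums / total


def assign_score(w: np.ndarray, cfg: ScoringConfig = ScoringConfig()) -> GleasonAssignment:
    """Apply the threshold rule to a weight vector (Benign, G3, G4, G5)."""
    w = np.asarray(w, dtype=np.float64)
    if w.shape != (4,):
        raise ValueError("expected a 4-vector of class weights")
    if np.isnan(w).any():
        raise ValueError("class weights contain NaN")
    final = np.where(w > cfg.threshold, w, 0.0)
    if cfg.tie_rule == "argmax" and not final.any():
        # degenerate all-below-threshold map: keep the argmax class
        final[int(np.argmax(w))] = w[int(np.argmax(w))]

    cancer = [(final[ch], ch) for ch in (1, 2, 3) if final[ch] > 0]
    if not cancer:
        return GleasonAssignment(w, final, None, None, 0)
    # largest final score first; exact ties favor the lower pattern
    cancer.sort(key=lambda t: (-t[0], t[1]))
    primary = _PATTERN_OF_CHANNEL[cancer[0][1]]
    secondary = _PATTERN_OF_CHANNEL[cancer[1][1]] if len(cancer) > 1 else primary
    return GleasonAssignment(w, final, primary, secondary, primary + secondary)


def score_cohort(maps: dict[str, ProbabilityMap] | list[tuple[str, ProbabilityMap]],
                 cfg: ScoringConfig = ScoringConfig()) -> pd.DataFrame:
    """Score a set of spots; returns rows (spot_id, primary, secondary, score).

    Benign spots get score 0 and empty pattern columns.  Rows are sorted
    by spot_id; duplicate ids are an error.
    """
    items = list(maps.items()) if isinstance(maps, dict) else list(maps)
    ids = [sid for sid, _ in items]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate spot ids: {dupes}")
    rows = []
    for sid, pmap in sorted(items, key=lambda t: t[0]):
        a = assign_score(class_weights(pmap), cfg)
        rows.append({"spot_id": sid,
                     "primary": a.primary if a.primary else pd.NA,
                     "secondary": a.secondary if a.secondary else pd.NA,
                     "score": a.composite})
    return pd.DataFrame(rows, columns=["spot_id", "primary", "secondary", "score"])
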