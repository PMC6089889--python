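"""Desk-scale end-to-end study: train, annotate, score, evaluate.

This is the package's self-contained counterpart of a full grading
experiment: a synthetic cohort is generated at half resolution
(1550-px spots, 375/187/125 patch geometry), a small classifier
(width multiplier 0.25, input 96) is trained from scratch with balanced
augmented batches, converted to a pixel annotator, and the held-out
spots are scored and compared with their ground-truth composite scores.
Problem sizes are chosen so a complete run takes a few minutes on one
CPU core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import (
    NetworkConfig,
    TrainConfig,
    build_network,
    evaluate_macro_recall,
    train,
)
from .fcn import convert_to_fcn, probability_map
from .patches import PatchDataset, PatchGeometry
from .scoring import score_cohort
from .synthetic import CohortFixture, generate_cohort

__all__ = ["DeskScaleSettings", "DeskScaleResult", "prepare_desk_data",
           "desk_scale_run", "desk_scale_study"]

#: half-resolution geometry with the small network's 96-px input crop
DESK_GEOMETRY = PatchGeometry(patch_size=375, step=187, label_window=125,
                              resize_to=125, crop_size=96)


@dataclass(frozen=True)
class DeskScaleSettings:
    n_train_spots: int = 20
    n_holdout_spots: int = 10
    spot_size_px: int = 1550
    width_multiplier: float = 0.25
    input_size: int = 96
    iterations: int = 2000
    batch_size: int = 32
    eval_interval: int = 500


@dataclass
class DeskScaleResult:
    macro_recall: float             # held-out patch-level balanced accuracy
    spot_agreement: float           # exact composite-score agreement
    scores: pd.DataFrame            # spot_id, predicted, true
    final_loss: float
    history: object = field(repr=False, default=None)


def prepare_desk_data(cohort_seed: int,
                      settings: DeskScaleSettings = DeskScaleSettings()):
    """Generate the cohort and patch datasets shared by training runs."""
    n = settings.n_train_spots + settings.n_holdout_spots
    cohort = generate_cohort(n, rng_seed=cohort_seed,
                             spot_size_px=settings.spot_size_px)
    train_spots = [s.realize() for s in cohort.spots[:settings.n_train_spots]]
    hold_spots = [s.realize() for s in cohort.spots[settings.n_train_spots:]]
    ds_train = PatchDataset.from_spots(train_spots, DESK_GEOMETRY)
    ds_hold = PatchDataset.from_spots(hold_spots, DESK_GEOMETRY)
    return cohort, hold_spots, ds_train, ds_hold


def desk_scale_run(train_seed: int, cohort: CohortFixture, hold_spots,
                   ds_train: PatchDataset, ds_hold: PatchDataset,
                   settings: DeskScaleSettings = DeskScaleSettings()
                   ) -> DeskScaleResult:
    """One training run plus spot-level scoring of the held-out spots."""
    clf = build_network(NetworkConfig(
        width_multiplier=settings.width_multiplier,
        input_size=settings.input_size, rng_seed=train_seed))
    history = train(clf, ds_train,
                    TrainConfig(mode="scratch",
                                iterations=settings.iterations,
                                batch_size=settings.batch_size,
                                eval_interval=settings.eval_interval,
                                rng_seed=train_seed),
                    holdout=ds_hold)
    recall = evaluate_macro_recall(clf, ds_hold)

    annotator = convert_to_fcn(clf, model_id=f"desk-seed{train_seed}")
    scale = DESK_GEOMETRY.resize_to / DESK_GEOMETRY.patch_size
    maps = {}
    for spot in hold_spots:
        # annotated tissue is ground truth here; detection is exercised
        # separately in the tissue module
        tissue = spot.mask > 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            maps[spot.spot_id] = probability_map(annotator, spot.image,
                                                 tissue, working_scale=scale)
    table = score_cohort(maps)
    truth = cohort.clinical.set_index("spot_id")["true_score"]
    table = table.assign(true=[truth[sid] for sid in table["spot_id"]])
    agreement = float((table["score"] == table["true"]).mean())
    return DeskScaleResult(macro_recall=float(recall),
                           spot_agreement=agreement,
                           scores=table,
                           final_loss=float(np.mean(history.loss[-50:])),
                           history=history)


def desk_scale_study(train_seeds=(0, 1, 2), cohort_seed: int = 42,
                     settings: DeskScaleSettings = DeskScaleSettings()
                     ) -> list[DeskScaleResult]:
    """Repeat the desk-scale run over training seeds on one shared cohort."""
    cohort, hold_spots, ds_train, ds_hold = prepare_desk_data(
        cohort_seed, settings)
    return [desk_scale_run(seed, cohort, hold_spots, ds_train, ds_hold,
                           settings)
            for seed in train_seeds]
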