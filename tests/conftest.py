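"""Shared fixtures: a small synthetic cohort and a quickly trained model.

All randomness is seeded; session-scoped fixtures are shared across test
modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from tmagleason.classifier import NetworkConfig, TrainConfig, build_network, train
from tmagleason.patches import PatchDataset, PatchGeometry
from tmagleason.synthetic import generate_cohort

#: half-resolution study geometry (1550-px spots), network input 96
HALF96 = PatchGeometry(patch_size=375, step=187, label_window=125,
                       resize_to=125, crop_size=96)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight half-resolution spots with clinical records (lazy rasters)."""
    return generate_cohort(8, rng_seed=11, spot_size_px=1550)


@pytest.fixture(scope="session")
def small_spots(small_cohort):
    return [s.realize() for s in small_cohort.spots]


@pytest.fixture(scope="session")
def small_dataset(small_spots):
    ds = PatchDataset.from_spots(small_spots, HALF96)
    assert all(np.bincount(ds.labels, minlength=4) > 0)
    return ds


@pytest.fixture(scope="session")
def smoke_model(small_dataset):
    """A tiny classifier trained briefly: enough to separate the textures."""
    clf = build_network(NetworkConfig(width_multiplier=0.25, input_size=96,
                                      rng_seed=1))
    history = train(clf, small_dataset,
                    TrainConfig(iterations=250, eval_interval=250, rng_seed=1))
    return clf, history
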