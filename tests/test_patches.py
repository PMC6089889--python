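"""Patch extraction, labeling rule, augmentation and balanced batches."""

import numpy as np
import pytest

from tmagleason.patches import (
    CLASS_NAMES,
    HALF_GEOMETRY,
    PatchDataset,
    PatchGeometry,
    augment,
    augment_batch,
    balanced_batches,
    extract_patches,
)
from tmagleason.synthetic import AnnotatedSpot

GEOM = HALF_GEOMETRY  # 375/187/125 at 1550-px spots


def _spot(mask, spot_id="s0"):
    image = np.zeros(mask.shape + (3,), dtype=np.uint8)
    return AnnotatedSpot(spot_id, image, mask.astype(np.uint8))


class TestExtractPatches:
    def test_uniform_spot_yields_full_grid(self):
        """A fully single-labeled spot produces the complete 7x7 grid."""
        mask = np.full((1550, 1550), 2, dtype=np.uint8)  # all G3
        patches = extract_patches(_spot(mask), GEOM)
        expected = ((1550 - GEOM.patch_size) // GEOM.step + 1) ** 2
        assert len(patches) == expected == 49
        assert all(p.label_name == "G3" for p in patches)

    def test_mixed_central_window_discarded(self):
        mask = np.full((1550, 1550), 2, dtype=np.uint8)
        mask[:, 775:] = 3                   # G3 | G4 split down the middle
        patches = extract_patches(_spot(mask), GEOM)
        o, lw = GEOM.window_offset, GEOM.label_window
        for p in patches:
            r, c = p.top_left
            window = mask[r + o:r + o + lw, c + o:c + o + lw]
            labels = np.unique(window)
            assert len(labels[labels != 0]) == 1
        # straddling candidates exist and were dropped
        assert len(patches) < 49

    def test_unannotated_spot_yields_nothing(self):
        mask = np.zeros((1550, 1550), dtype=np.uint8)
        assert extract_patches(_spot(mask), GEOM) == []

    def test_background_inside_window_ignored(self):
        """Unannotated pixels in the window do not veto a single label."""
        mask = np.zeros((400, 400), dtype=np.uint8)
        mask[::2, ::2] = 4                  # sparse G5 over background
        geom = PatchGeometry(patch_size=300, step=300, label_window=100,
                             resize_to=100, crop_size=64)
        patches = extract_patches(_spot(mask), geom)
        assert len(patches) == 1
        assert patches[0].label_name == "G5"

    def test_small_spot_warns_and_returns_empty(self):
        mask = np.full((100, 100), 2, dtype=np.uint8)
        with pytest.warns(UserWarning, match="smaller than patch"):
            assert extract_patches(_spot(mask), GEOM) == []

    def test_extraction_deterministic(self, small_spots):
        a = extract_patches(small_spots[0], GEOM)
        b = extract_patches(small_spots[0], GEOM)
        assert [(p.top_left, p.label) for p in a] == \
               [(p.top_left, p.label) for p in b]

    def test_emitted_windows_single_labeled(self, small_spots):
        """Round-trip audit of the central-window rule on generated spots."""
        o, lw = GEOM.window_offset, GEOM.label_window
        for spot in small_spots[:3]:
            for p in extract_patches(spot, GEOM):
                r, c = p.top_left
                window = spot.mask[r + o:r + o + lw, c + o:c + o + lw]
                labels = np.unique(window)
                labels = labels[labels != 0]
                assert labels.size == 1
                assert labels[0] - 1 == p.label


class TestAugment:
    def test_deterministic_given_seed(self):
        img = np.random.default_rng(0).integers(0, 255, (125, 125, 3),
                                                dtype=np.uint8)
        a = augment(img, 96, np.random.default_rng(5))
        b = augment(img, 96, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_output_shape(self):
        img = np.zeros((125, 125, 3), dtype=np.uint8)
        assert augment(img, 96, np.random.default_rng(0)).shape == (96, 96, 3)

    def test_no_rng_gives_center_crop(self):
        img = np.random.default_rng(1).integers(0, 255, (125, 125, 3),
                                                dtype=np.uint8)
        out = augment(img, 96, rng=None)
        off = (125 - 96) // 2
        expected = img[off:off + 96, off:off + 96].astype(np.float32) / 255.0
        assert np.allclose(out, expected)

    def test_batch_values_stay_in_unit_range(self):
        rng = np.random.default_rng(2)
        x = rng.random((8, 125, 125, 3), dtype=np.float32)
        out = augment_batch(x, 96, rng)
        assert out.shape == (8, 96, 96, 3)
        assert out.min() >= 0.0 and out.max() <= 1.0


class TestBalancedBatches:
    def test_every_batch_has_equal_class_counts(self, small_dataset):
        stream = balanced_batches(small_dataset, batch_size=32,
                                  rng=np.random.default_rng(0))
        for _ in range(5):
            idx = next(stream)
            counts = np.bincount(small_dataset.labels[idx], minlength=4)
            assert (counts == 8).all()

    def test_single_patch_per_class_repeats(self):
        images = np.zeros((4, 8, 8, 3), dtype=np.uint8)
        ds = PatchDataset(images=images, labels=np.arange(4),
                          spot_ids=["a"] * 4, top_lefts=[(0, 0)] * 4)
        idx = next(balanced_batches(ds, 32, np.random.default_rng(0)))
        counts = np.bincount(idx, minlength=4)
        assert (counts == 8).all()

    def test_missing_class_raises_with_name(self, small_dataset):
        sub = small_dataset.subset(np.flatnonzero(small_dataset.labels != 2))
        with pytest.raises(ValueError, match="G4"):
            balanced_batches(sub, 32)

    def test_indivisible_batch_size_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            balanced_batches(small_dataset, batch_size=30)

    def test_long_run_marginals_uniform(self, small_dataset):
        stream = balanced_batches(small_dataset, batch_size=32,
                                  rng=np.random.default_rng(3))
        counts = np.zeros(len(small_dataset))
        n_batches = 2000
        for _ in range(n_batches):
            np.add.at(counts, next(stream), 1)
        per_class = np.zeros(4)
        for c in range(4):
            per_class[c] = counts[small_dataset.labels == c].sum()
        freq = per_class / counts.sum()
        assert np.allclose(freq, 0.25, atol=0.01)
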