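"""Labeled training patches from annotated TMA spots.

A spot image is tiled on a fixed grid (patch 750 px, step 375 px at full
resolution).  Each candidate patch is labeled by the annotation found in
its central 250 x 250 window: if the window contains exactly one
distinct nonzero mask label, the patch receives that label; windows with
no annotation, or with more than one, are discarded.  Kept patches are
resized (750 -> 250) and randomly cropped/augmented to the network input
size during training, and streamed as class-balanced mini-batches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "CLASS_NAMES",
    "MASK_BACKGROUND",
    "PatchGeometry",
    "FULL_GEOMETRY",
    "HALF_GEOMETRY",
    "LabeledPatch",
    "extract_patches",
    "resize_patch",
    "augment",
    "augment_batch",
    "PatchDataset",
    "balanced_batches",
]

#: ordered class names; mask encoding is 0 = unannotated, then 1 + class index
CLASS_NAMES = ("Benign", "G3", "G4", "G5")
MASK_BACKGROUND = 0


@dataclass(frozen=True)
class PatchGeometry:
    """Patch sampling geometry (pixels at working resolution)."""

    patch_size: int = 750
    step: int = 375
    label_window: int = 250
    resize_to: int = 250
    crop_size: int = 224

    def __post_init__(self):
        if self.label_window > self.patch_size:
            raise ValueError("label_window must not exceed patch_size")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.crop_size > self.resize_to:
            raise ValueError("crop_size must not exceed resize_to")

    @property
    def window_offset(self) -> int:
        return (self.patch_size - self.label_window) // 2


FULL_GEOMETRY = PatchGeometry()
#: halved geometry used by the desk-scale profile (spot side 1550 px)
HALF_GEOMETRY = PatchGeometry(patch_size=375, step=187, label_window=125,
                              resize_to=125, crop_size=112)


@dataclass
class LabeledPatch:
    spot_id: str
    top_left: tuple[int, int]
    label: int                      # index into CLASS_NAMES
    pixels: np.ndarray              # (patch, patch, 3) uint8

    @property
    def label_name(self) -> str:
        return CLASS_NAMES[self.label]


def extract_patches(spot, geom: PatchGeometry = FULL_GEOMETRY) -> list[LabeledPatch]:
    """All grid patches of ``spot`` whose central window is single-labeled.

    ``spot`` needs ``image`` (H, W, 3), ``mask`` (H, W) with the 0..4
    encoding and ``spot_id``.  The grid is anchored at (0, 0); patches
    that do not fit entirely inside the spot are skipped.
    """
    image, mask = spot.image, spot.mask
    H, W = mask.shape
    p, s = geom.patch_size, geom.step
    if H < p or W < p:
        warnings.warn(f"spot {spot.spot_id} smaller than patch size {p}; "
                      "no patches extracted")
        return []
    o, lw = geom.window_offset, geom.label_window
    out: list[LabeledPatch] = []
    for r in range(0, H - p + 1, s):
        for c in range(0, W - p + 1, s):
            window = mask[r + o:r + o + lw, c + o:c + o + lw]
            labels = np.unique(window)
            labels = labels[labels != MASK_BACKGROUND]
            if labels.size != 1:
                continue
            out.append(LabeledPatch(
                spot_id=spot.spot_id,
                top_left=(r, c),
                label=int(labels[0]) - 1,
                pixels=image[r:r + p, c:c + p],
            ))
    return out


def resize_patch(pixels: np.ndarray, size: int) -> np.ndarray:
    """Anti-aliased resize of one RGB patch to (size, size, 3) uint8."""
    if pixels.shape[0] == size and pixels.shape[1] == size:
        return np.ascontiguousarray(pixels)
    out = _sk_resize(pixels, (size, size), order=1, anti_aliasing=True,
                     preserve_range=True)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def _color_jitter_batch(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mild per-sample brightness/contrast/saturation scaling + hue shift.

    Scales are drawn from [0.9, 1.1] and the hue shift from +-0.02, small
    enough to preserve the H&E stain identity of a patch.
    """
    B = x.shape[0]
    bright = rng.uniform(0.9, 1.1, size=B).astype(np.float32)
    contrast = rng.uniform(0.9, 1.1, size=B).astype(np.float32)
    sat = rng.uniform(0.9, 1.1, size=B).astype(np.float32)
    hue = rng.uniform(-0.02, 0.02, size=B).astype(np.float32)

    # brightness, contrast (about the per-sample mean), saturation (lerp
    # toward luminance) and hue (rotation about the gray axis) are all
    # affine in RGB, so they collapse into one 3x3 matrix + offset per
    # sample, applied in a single einsum pass.
    lum = np.array([0.299, 0.587, 0.114], dtype=np.float32)
    eye = np.eye(3, dtype=np.float32)
    S = sat[:, None, None] * eye + (1 - sat)[:, None, None] * lum[None, :]
    theta = hue * (2.0 * np.float32(np.pi))
    cos, sin = np.cos(theta), np.sin(theta)
    K = np.array([[0, -1, 1], [1, 0, -1], [-1, 1, 0]],
                 dtype=np.float32) / np.float32(np.sqrt(3.0))
    J = np.full((3, 3), 1.0 / 3.0, dtype=np.float32)
    R = (cos[:, None, None] * eye + sin[:, None, None] * K
         + (1 - cos)[:, None, None] * J)
    M = np.einsum("bij,bjk->bik", R, S) * (contrast * bright)[:, None, None]
    mean0 = x.mean(axis=(1, 2, 3))
    offset = ((1 - contrast) * bright * mean0).astype(np.float32)
    out = (x.reshape(B, -1, 3) @ M.transpose(0, 2, 1)).reshape(x.shape)
    out += offset[:, None, None, None]
    return np.clip(out, 0.0, 1.0)


def augment_batch(x: np.ndarray, crop_size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Random crop, 90-degree rotation, flips and color jitter for a batch.

    ``x`` is float32 in [0, 1] of shape (B, r, r, 3) with r >= crop_size.
    """
    B, r = x.shape[0], x.shape[1]
    span = r - crop_size
    rows = rng.integers(0, span + 1, size=B)
    cols = rng.integers(0, span + 1, size=B)
    rots = rng.integers(0, 4, size=B)
    flips = rng.random(size=(B, 2)) < 0.5
    out = np.empty((B, crop_size, crop_size, 3), dtype=np.float32)
    for i in range(B):
        v = x[i, rows[i]:rows[i] + crop_size, cols[i]:cols[i] + crop_size]
        if rots[i]:
            v = np.rot90(v, k=int(rots[i]))
        if flips[i, 0]:
            v = v[::-1]
        if flips[i, 1]:
            v = v[:, ::-1]
        out[i] = v
    return _color_jitter_batch(out, rng)


def augment(patch_image: np.ndarray, crop_size: int,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """One augmented view of a resized patch image.

    With ``rng=None`` all randomness is disabled and the deterministic
    fallback — the center crop of the resized patch — is returned.
    Input may be uint8 or float in [0, 1]; output is float32 in [0, 1]
    of shape (crop_size, crop_size, 3).
    """
    x = patch_image.astype(np.float32)
    if patch_image.dtype == np.uint8:
        x /= 255.0
    if rng is None:
        off = (x.shape[0] - crop_size) // 2
        return x[off:off + crop_size, off:off + crop_size].copy()
    return augment_batch(x[None], crop_size, rng)[0]


@dataclass
class PatchDataset:
    """Resized labeled patches held in memory for training/evaluation."""

    images: np.ndarray                  # (N, r, r, 3) uint8
    labels: np.ndarray                  # (N,) int64, index into CLASS_NAMES
    spot_ids: list[str]
    top_lefts: list[tuple[int, int]]
    geometry: PatchGeometry = field(default=FULL_GEOMETRY)

    def __len__(self) -> int:
        return self.images.shape[0]

    @classmethod
    def from_spots(cls, spots, geom: PatchGeometry = FULL_GEOMETRY) -> "PatchDataset":
        imgs, labels, ids, tls = [], [], [], []
        for spot in spots:
            for patch in extract_patches(spot, geom):
                imgs.append(resize_patch(patch.pixels, geom.resize_to))
                labels.append(patch.label)
                ids.append(patch.spot_id)
                tls.append(patch.top_left)
        if imgs:
            images = np.stack(imgs)
        else:
            images = np.zeros((0, geom.resize_to, geom.resize_to, 3), np.uint8)
        return cls(images=images,
                   labels=np.asarray(labels, dtype=np.int64),
                   spot_ids=ids, top_lefts=tls, geometry=geom)

    def channel_mean(self) -> np.ndarray:
        """Per-channel mean of the dataset on the [0, 1] scale."""
        if len(self) == 0:
            return np.zeros(3, dtype=np.float32)
        return (self.images.mean(axis=(0, 1, 2)) / 255.0).astype(np.float32)

    def center_crops(self, crop_size: int, start: int = 0,
                     stop: int | None = None) -> np.ndarray:
        sel = self.images[start:stop]
        off = (sel.shape[1] - crop_size) // 2
        return sel[:, off:off + crop_size, off:off + crop_size]

    def subset(self, idx) -> "PatchDataset":
        idx = np.asarray(idx)
        return PatchDataset(images=self.images[idx], labels=self.labels[idx],
                           spot_ids=[self.spot_ids[i] for i in idx],
                           top_lefts=[self.top_lefts[i] for i in idx],
                           geometry=self.geometry)

    def manifest(self):
        """Patch manifest as a DataFrame (spot_id, row, col, label)."""
        import pandas as pd
        return pd.DataFrame({
            "spot_id": self.spot_ids,
            "row": [t[0] for t in self.top_lefts],
            "col": [t[1] for t in self.top_lefts],
            "label": [CLASS_NAMES[l] for l in self.labels],
        })


def balanced_batches(dataset: PatchDataset, batch_size: int = 32,
                     rng: np.random.Generator | None = None):
    """Endless stream of index batches with equal per-class counts.

    Each batch holds exactly ``batch_size / 4`` examples per class,
    sampled uniformly with replacement within class.
    """
    if batch_size % len(CLASS_NAMES) != 0:
        raise ValueError("batch_size must be divisible by the number of classes")
    rng = rng or np.random.default_rng()
    per_class = batch_size // len(CLASS_NAMES)
    pools = []
    for c, name in enumerate(CLASS_NAMES):
        idx = np.flatnonzero(dataset.labels == c)
        if idx.size == 0:
            raise ValueError(f"class {name!r} has no examples in the dataset")
        pools.append(idx)

    def _gen():
        while True:
            batch = np.concatenate([
                pool[rng.integers(0, pool.size, size=per_class)]
                for pool in pools])
            rng.shuffle(batch)
            yield batch

    return _gen()
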