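"""Fully convolutional conversion of the patch classifier.

To annotate whole spots at pixel level, the trained classifier's global
average pooling (which sees a 7x7 feature map for 224-px patches) is
replaced by a local average pooling of that same window size with
stride 1, and the dense classification layer by an equivalent 1x1
convolution; softmax is applied per spatial location and the class map
is restored to image resolution by nearest-neighbour upsampling with
factor 32 (the network's output stride).

Whole spots are presented to the network at the scale the classifier
was trained at (patches are resized by resize_to / patch_size before
training, so spots are downscaled by the same factor), and the finished
map is resized back to spot resolution.  Inference can run tile-wise
with enough context overlap (the receptive field) that tiled and
untiled maps agree to float precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .classifier import PatchClassifier
from .synthetic import ProbabilityMap

__all__ = ["PixelAnnotator", "convert_to_fcn", "probability_map"]


def _avg_pool_same(f: np.ndarray, k: int) -> np.ndarray:
    """k x k mean pooling, stride 1, same size; border windows are
    averaged over their valid part only (no zero dilution)."""
    h, w, c = f.shape
    half = k // 2
    cs = np.zeros((h + 1, w + 1, c), dtype=np.float64)
    cs[1:, 1:] = f
    np.cumsum(cs, axis=0, out=cs)
    np.cumsum(cs, axis=1, out=cs)
    i = np.arange(h)
    j = np.arange(w)
    r0 = np.clip(i - half, 0, h)
    r1 = np.clip(i + half + 1, 0, h)
    c0 = np.clip(j - half, 0, w)
    c1 = np.clip(j + half + 1, 0, w)
    S = (cs[r1[:, None], c1[None, :]] - cs[r0[:, None], c1[None, :]]
         - cs[r1[:, None], c0[None, :]] + cs[r0[:, None], c0[None, :]])
    counts = ((r1 - r0)[:, None] * (c1 - c0)[None, :]).astype(np.float64)
    return (S / counts[..., None]).astype(np.float32)


def _avg_pool_valid(f: np.ndarray, k: int) -> np.ndarray:
    h, w, c = f.shape
    if h < k or w < k:
        raise ValueError(f"feature map {h}x{w} smaller than pool window {k}")
    cs = np.zeros((h + 1, w + 1, c), dtype=np.float64)
    cs[1:, 1:] = f
    np.cumsum(cs, axis=0, out=cs)
    np.cumsum(cs, axis=1, out=cs)
    S = (cs[k:, k:] - cs[:-k, k:] - cs[k:, :-k] + cs[:-k, :-k])
    return (S / (k * k)).astype(np.float32)


@dataclass
class PixelAnnotator:
    """The classifier re-expressed as a sliding-window pixel annotator."""

    classifier: PatchClassifier
    pool_size: int                  # training-time pre-pooling map side
    output_stride: int = 32
    model_id: str = "model"

    @property
    def receptive_field(self) -> int:
        """Receptive field (input px) of one pre-upsampling location."""
        rf, jump = 1, 1
        for layer in self.classifier.conv_stack:
            if isinstance(layer, (nn.Conv2d, nn.DepthwiseConv2d)):
                rf += (layer.k - 1) * jump
                jump *= layer.stride
        return rf + (self.pool_size - 1) * jump

    def class_map(self, x: np.ndarray, pool_padding: str = "same") -> np.ndarray:
        """Pre-upsampling probability map (h, w, 4) of a normalized image.

        ``x`` is (H, W, 3) float32, already normalized like training
        input.  With ``pool_padding="valid"`` only complete pooling
        windows are evaluated (a single location for one training-size
        patch, reproducing ``predict_patch``).
        """
        f = self.classifier.features(x[None])[0]
        pooled = (_avg_pool_same(f, self.pool_size) if pool_padding == "same"
                  else _avg_pool_valid(f, self.pool_size))
        head = self.classifier.dense_layer
        logits = pooled @ head.weight.value + head.bias.value
        return nn.softmax(logits, axis=-1)

    def class_map_tiled(self, x: np.ndarray, core: int = 256) -> np.ndarray:
        """Tile-wise evaluation of ``class_map`` (same padding).

        Tiles are aligned to the output stride and carry a context
        margin covering the receptive field, so the stitched map equals
        the untiled one up to float roundoff.
        """
        s = self.output_stride
        H, W = x.shape[:2]
        core = max((core // s) * s, s)
        margin = int(np.ceil((self.receptive_field - 1) / 2 / s)) * s
        h_out = -(-H // s)
        w_out = -(-W // s)
        out = np.empty((h_out, w_out, 4), dtype=np.float32)
        for r0 in range(0, H, core):
            r1 = min(r0 + core, H)
            cr0 = max(r0 - margin, 0)
            cr1 = min(r1 + margin, H)
            for c0 in range(0, W, core):
                c1 = min(c0 + core, W)
                cc0 = max(c0 - margin, 0)
                cc1 = min(c1 + margin, W)
                tile_map = self.class_map(x[cr0:cr1, cc0:cc1])
                orow = r0 // s
                ocol = c0 // s
                tr0 = (r0 - cr0) // s
                tc0 = (c0 - cc0) // s
                nr = -(-(r1 - r0) // s) if r1 < H else h_out - orow
                nc = -(-(c1 - c0) // s) if c1 < W else w_out - ocol
                out[orow:orow + nr, ocol:ocol + nc] = \
                    tile_map[tr0:tr0 + nr, tc0:tc0 + nc]
        return out

    def upsample(self, class_map: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Nearest-neighbour x32 upsampling, cropped to ``shape``."""
        s = self.output_stride
        up = np.repeat(np.repeat(class_map, s, axis=0), s, axis=1)
        return up[:shape[0], :shape[1]]


def convert_to_fcn(classifier: PatchClassifier, model_id: str = "model") -> PixelAnnotator:
    """Swap global pooling for local average pooling with stride 1.

    The pooling window equals the classifier's own pre-pooling feature
    map side at its training input size (7 for 224-px inputs).
    """
    fm = classifier.feature_map_size()
    if fm < 1:
        raise ValueError(
            f"input size {classifier.config.input_size} leaves no spatial "
            "feature map to pool")
    expected = classifier.config.input_size // 32
    if fm != expected:
        raise ValueError(
            f"pre-pooling map is {fm}x{fm} but input geometry implies "
            f"{expected}x{expected}; cannot convert")
    return PixelAnnotator(classifier=classifier, pool_size=fm,
                          model_id=model_id)


def probability_map(annotator: PixelAnnotator,
                    spot_image: np.ndarray,
                    tissue_mask: np.ndarray,
                    working_scale: float = 1.0,
                    tile: int | None = None) -> ProbabilityMap:
    """Whole-spot 4-channel probability map at spot resolution.

    ``working_scale`` is the factor by which the spot is downscaled
    before entering the network (use resize_to / patch_size of the
    training geometry, e.g. 250/750); the finished map is restored to
    the spot's own resolution.  Channels are zeroed outside
    ``tissue_mask``.
    """
    if spot_image.shape[:2] != tissue_mask.shape:
        raise ValueError("image and tissue mask shapes differ")
    H, W = tissue_mask.shape
    meta = {"model_id": annotator.model_id,
            "working_scale": working_scale,
            "border_band_px": int(np.ceil(
                annotator.receptive_field / 2 / working_scale))}
    if not tissue_mask.any():
        warnings.warn("empty tissue mask: returning all-zero probability map")
        return ProbabilityMap(np.zeros((H, W, 4), np.float32),
                              tissue_mask.astype(bool), meta)

    if working_scale != 1.0:
        hs = max(int(round(H * working_scale)), 32)
        ws = max(int(round(W * working_scale)), 32)
        small = _sk_resize(spot_image, (hs, ws), order=1, anti_aliasing=True,
                           preserve_range=True).astype(np.float32) / 255.0
    else:
        small = spot_image.astype(np.float32) / 255.0
    small -= annotator.classifier.input_mean

    if tile is None:
        cmap = annotator.class_map(small)
    else:
        cmap = annotator.class_map_tiled(small, core=tile)
    up = annotator.upsample(cmap, small.shape[:2])
    if up.shape[:2] != (H, W):
        up = _sk_resize(up, (H, W), order=0, preserve_range=True,
                        anti_aliasing=False).astype(np.float32)
    up = up * tissue_mask[..., None]
    return ProbabilityMap(up.astype(np.float32), tissue_mask.astype(bool), meta)
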