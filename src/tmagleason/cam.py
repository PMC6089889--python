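"""Class activation maps for confidently classified patches.

A CAM projects the classification layer's class-specific weights back
onto the last convolutional feature maps: the raw map is the weighted
sum over channels, negatives are clipped, the result is scaled so its
maximum is 1 (or left all-zero if nothing is positive) and upsampled to
patch resolution.  Patches are pre-selected when the model predicts the
true class with probability above 0.8 (strict), mirroring how
high-confidence examples are chosen for visual inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .classifier import PatchClassifier
from .patches import CLASS_NAMES

__all__ = ["ActivationMap", "select_confident", "class_activation_map",
           "render_triptych"]


@dataclass
class ActivationMap:
    heatmap: np.ndarray             # (H, W) float in [0, 1]
    target_class: int
    confidence: float

    @property
    def target_name(self) -> str:
        return CLASS_NAMES[self.target_class]


def select_confident(patches: np.ndarray, labels: np.ndarray,
                     classifier: PatchClassifier,
                     threshold: float = 0.8) -> np.ndarray:
    """Indices of correctly classified patches with probability > threshold.

    ``patches`` is a normalized batch (B, s, s, 3); the comparison is
    strict, so a probability of exactly ``threshold`` is excluded.
    """
    probs = classifier.predict_proba(patches)
    pred = probs.argmax(axis=1)
    conf = probs[np.arange(len(probs)), pred]
    keep = (pred == np.asarray(labels)) & (conf > threshold)
    return np.flatnonzero(keep)


def class_activation_map(classifier: PatchClassifier, patch: np.ndarray,
                         target_class: int) -> ActivationMap:
    """CAM of one normalized patch (s, s, 3) for ``target_class``."""
    if patch.ndim != 3:
        raise ValueError("expected a single patch (H, W, 3)")
    feats = classifier.features(patch[None])[0]          # (h, w, C)
    head = classifier.dense_layer
    weights = head.weight.value[:, target_class]         # (C,)
    raw = feats @ weights
    raw = np.clip(raw, 0.0, None)
    peak = raw.max()
    heat = raw / peak if peak > 0 else raw
    heat = _sk_resize(heat, patch.shape[:2], order=1, preserve_range=True,
                      anti_aliasing=False)
    heat = np.clip(heat, 0.0, 1.0)
    probs = classifier.predict_proba(patch[None])[0]
    return ActivationMap(heatmap=heat.astype(np.float32),
                         target_class=int(target_class),
                         confidence=float(probs[target_class]))


def render_triptych(patch_rgb: np.ndarray, cam: ActivationMap, out_path=None):
    """Original / heatmap-overlay / highlighted-only figure, 3 columns."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(9, 3.2))
    axes[0].imshow(patch_rgb)
    axes[0].set_title(f"{cam.target_name} (p={cam.confidence:.2f})")
    axes[1].imshow(patch_rgb)
    axes[1].imshow(cam.heatmap, cmap="jet", alpha=0.45, vmin=0, vmax=1)
    axes[1].set_title("CAM overlay")
    masked = (patch_rgb.astype(np.float32) * cam.heatmap[..., None])
    axes[2].imshow(masked.astype(np.uint8))
    axes[2].set_title("highlighted region")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
        return None
    return fig
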