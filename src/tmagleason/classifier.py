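"""Depthwise-separable convolutional patch classifier (4 Gleason classes).

The network follows the MobileNet-v1 layout: an initial strided 3x3
convolution, thirteen depthwise-separable blocks (3x3 per-channel
convolution, stride 2 at blocks 2/4/6/12, each followed by a 1x1
pointwise convolution that grows the channel count), global average
pooling, dropout and a dense softmax head over the four classes
(Benign, Gleason 3, Gleason 4, Gleason 5).  The width multiplier
``alpha`` scales every channel count: alpha=1 runs 32 -> 1024 channels,
the default alpha=0.5 runs 16 -> 512.

Training uses balanced mini-batches of augmented patch crops and
categorical cross-entropy, with Adam (lr 1e-3) when training from
scratch and Nesterov SGD (lr 1e-4, momentum 0.9) in fine-tune mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .patches import CLASS_NAMES, PatchDataset, augment_batch, balanced_batches

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "PatchClassifier",
    "TrainHistory",
    "build_network",
    "train",
    "predict_patch",
]

# (pointwise output channels at alpha=1, depthwise stride) for the 13 blocks
_BLOCK_LAYOUT = [
    (64, 1),
    (128, 2), (128, 1),
    (256, 2), (256, 1),
    (512, 2), (512, 1), (512, 1), (512, 1), (512, 1), (512, 1),
    (1024, 2), (1024, 1),
]


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters of the patch classifier."""

    width_multiplier: float = 0.5
    input_size: int = 224
    n_classes: int = 4
    dropout_rate: float = 0.2
    rng_seed: int = 0

    def __post_init__(self):
        if self.width_multiplier <= 0:
            raise ValueError("width_multiplier must be positive")
        if self.n_classes != 4:
            raise ValueError("this pipeline is defined for exactly 4 classes")


@dataclass
class TrainConfig:
    """Optimization settings for the two training regimes."""

    mode: str = "scratch"          # "scratch" (Adam) or "finetune" (Nesterov SGD)
    learning_rate: float | None = None
    momentum: float = 0.9
    iterations: int = 50_000
    batch_size: int = 32
    eval_interval: int = 250
    eval_batch: int = 128
    rng_seed: int = 0

    def __post_init__(self):
        if self.mode not in ("scratch", "finetune"):
            raise ValueError(f"unknown training mode {self.mode!r}")
        if self.learning_rate is None:
            self.learning_rate = 1e-3 if self.mode == "scratch" else 1e-4
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _scaled(base: int, alpha: float) -> int:
    c = base * alpha
    rounded = math.ceil(c)
    if abs(c - rounded) > 1e-9:
        warnings.warn(
            f"width multiplier {alpha} gives non-integer channel count {c}; "
            f"rounding up to {rounded}", stacklevel=3)
    return int(rounded)


class PatchClassifier:
    """The network plus the input normalization it was trained with."""

    def __init__(self, model: nn.Sequential, config: NetworkConfig):
        self.model = model
        self.config = config
        # per-channel mean of the training inputs (after scaling to [0,1])
        self.input_mean = np.zeros(3, dtype=np.float32)
        self._feature_cache = None

    # ---- architecture introspection -------------------------------------

    @property
    def first_conv_channels(self) -> int:
        return self.model.layers[0].out_ch

    @property
    def last_conv_channels(self) -> int:
        return self.dense_layer.weight.value.shape[0]

    @property
    def dense_layer(self) -> nn.Dense:
        return self.model.layers[-1]

    @property
    def conv_stack(self) -> list[nn.Layer]:
        """Layers up to (excluding) global average pooling."""
        idx = next(i for i, l in enumerate(self.model.layers)
                   if isinstance(l, nn.GlobalAvgPool))
        return self.model.layers[:idx]

    def feature_map_size(self, input_size: int | None = None) -> int:
        """Spatial side of the pre-pooling feature map (stride product 32)."""
        size = input_size if input_size is not None else self.config.input_size
        for layer in self.conv_stack:
            if isinstance(layer, (nn.Conv2d, nn.DepthwiseConv2d)) and layer.stride > 1:
                size = (size + 2 * (layer.k // 2) - layer.k) // layer.stride + 1
        return size

    def n_parameters(self) -> int:
        return self.model.n_parameters()

    # ---- inference -------------------------------------------------------

    def normalize(self, x: np.ndarray) -> np.ndarray:
        """uint8/float image batch -> centered float32 in roughly [-1, 1]."""
        x = np.asarray(x)
        if x.dtype == np.uint8:
            x = x.astype(np.float32) / 255.0
        else:
            x = x.astype(np.float32, copy=True)
        return x - self.input_mean

    def features(self, x: np.ndarray) -> np.ndarray:
        """Last convolutional feature map (B, h, w, C), eval mode."""
        for layer in self.conv_stack:
            x = layer.forward(x, train=False)
        return x

    def logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.model.forward(x, train=train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a normalized input batch (B, s, s, 3)."""
        s = self.config.input_size
        if x.ndim != 4 or x.shape[1] != s or x.shape[2] != s or x.shape[3] != 3:
            raise ValueError(
                f"expected input of shape (B, {s}, {s}, 3), got {x.shape}")
        return nn.softmax(self.logits(x, train=False))


def build_network(config: NetworkConfig) -> PatchClassifier:
    """Assemble the depthwise-separable classifier for ``config``."""
    rng = np.random.default_rng(config.rng_seed)
    alpha = config.width_multiplier
    layers: list[nn.Layer] = []
    c_in = _scaled(32, alpha)
    layers += [
        nn.Conv2d(3, c_in, 3, stride=2, padding="same", rng=rng, name="conv0",
                  input_grad=False),
        nn.BatchNormReLU(c_in, name="bn0"),
    ]
    for b, (c_base, stride) in enumerate(_BLOCK_LAYOUT, start=1):
        c_out = _scaled(c_base, alpha)
        layers += [
            nn.DepthwiseConv2d(c_in, 3, stride=stride, padding="same",
                               rng=rng, name=f"dw{b}"),
            nn.BatchNormReLU(c_in, name=f"bn{b}a"),
            nn.Conv2d(c_in, c_out, 1, stride=1, padding="valid",
                      rng=rng, name=f"pw{b}"),
            nn.BatchNormReLU(c_out, name=f"bn{b}b"),
        ]
        c_in = c_out
    layers += [
        nn.GlobalAvgPool(),
        nn.Dropout(config.dropout_rate, rng=np.random.default_rng(
            config.rng_seed + 1)),
        nn.Dense(c_in, config.n_classes, rng=rng, name="head"),
    ]
    return PatchClassifier(nn.Sequential(layers), config)


def predict_patch(classifier: PatchClassifier, patch: np.ndarray) -> np.ndarray:
    """Probability vector (Benign, G3, G4, G5) for one normalized crop."""
    if patch.ndim == 3:
        patch = patch[None]
    probs = classifier.predict_proba(patch)
    return probs[0] if probs.shape[0] == 1 else probs


@dataclass
class TrainHistory:
    iterations: list[int] = field(default_factory=list)
    loss: list[float] = field(default_factory=list)
    eval_iterations: list[int] = field(default_factory=list)
    macro_recall: list[float] = field(default_factory=list)


def _macro_recall_from_preds(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    recalls = []
    for c in range(len(CLASS_NAMES)):
        sel = y_true == c
        if sel.any():
            recalls.append(float((y_pred[sel] == c).mean()))
    return float(np.mean(recalls)) if recalls else float("nan")


def evaluate_macro_recall(classifier: PatchClassifier, dataset: PatchDataset,
                          batch: int = 64) -> float:
    """Balanced accuracy on center crops of a held-out patch dataset."""
    s = classifier.config.input_size
    preds = []
    for start in range(0, len(dataset), batch):
        x = dataset.center_crops(s, start, start + batch)
        x = classifier.normalize(x)
        preds.append(classifier.predict_proba(x).argmax(axis=1))
    return _macro_recall_from_preds(dataset.labels, np.concatenate(preds))


def train(classifier: PatchClassifier, dataset: PatchDataset, cfg: TrainConfig,
          holdout: PatchDataset | None = None) -> TrainHistory:
    """Train in place with balanced, augmented mini-batches.

    Every sample is augmented (random crop / rotation / flip / color
    jitter); evaluation on ``holdout`` happens every ``eval_interval``
    iterations and is recorded in the returned history.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    classifier.input_mean = dataset.channel_mean()
    for layer in classifier.model.layers:
        if isinstance(layer, nn.Dropout):
            layer.rng = np.random.default_rng(rng.integers(2**31))
    params = classifier.model.params
    if cfg.mode == "scratch":
        opt = nn.Adam(params, lr=cfg.learning_rate)
    else:
        opt = nn.NesterovSGD(params, lr=cfg.learning_rate, momentum=cfg.momentum)

    crop = classifier.config.input_size
    history = TrainHistory()
    batches = balanced_batches(dataset, batch_size=cfg.batch_size, rng=rng)
    for it, idx in zip(range(1, cfg.iterations + 1), batches):
        x = dataset.images[idx].astype(np.float32) / 255.0
        x = augment_batch(x, crop, rng)
        x -= classifier.input_mean
        y = dataset.labels[idx]
        logits = classifier.logits(x, train=True)
        loss, grad, _ = nn.softmax_cross_entropy(logits, y)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"training diverged: non-finite loss {loss} at iteration {it}")
        classifier.model.zero_grad()
        classifier.model.backward(grad)
        opt.step()
        history.iterations.append(it)
        history.loss.append(loss)
        if holdout is not None and (it % cfg.eval_interval == 0
                                    or it == cfg.iterations):
            history.eval_iterations.append(it)
            history.macro_recall.append(
                evaluate_macro_recall(classifier, holdout))
    return history
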