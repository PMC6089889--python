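"""Automatic tissue detection in TMA spot images.

Pipeline: Gaussian smoothing of the grayscale intensity, Otsu
thresholding (tissue is the darker class; slides are bright-field with a
near-white background), then morphological dilation followed by erosion
(a closing) with a disk structuring element, which fills small holes
such as gland lumens without bridging separate tissue fragments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import dilation, disk, erosion

__all__ = ["TissueMaskParams", "detect_tissue", "rgb_to_gray"]

#: ITU-R 601 luminance weights used for grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class TissueMaskParams:
    gaussian_sigma: float = 2.0     # px
    morph_radius: int = 10          # px, disk structuring element

    def __post_init__(self):
        if self.gaussian_sigma <= 0:
            raise ValueError("gaussian_sigma must be > 0")
        if self.morph_radius < 1:
            raise ValueError("morph_radius must be >= 1")


def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Luminance grayscale in [0, 1] from RGB or grayscale input."""
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = img.astype(np.float64) / 255.0
    if img.ndim == 3:
        return img @ _LUMA
    return img.astype(np.float64)


def detect_tissue(image: np.ndarray,
                  params: TissueMaskParams = TissueMaskParams()) -> np.ndarray:
    """Binary tissue mask of the same spatial shape as ``image``.

    On a constant-intensity image the Otsu threshold is undefined; an
    empty mask is returned with a warning.
    """
    gray = rgb_to_gray(image)
    if gray.size == 0:
        raise ValueError("empty image")
    smooth = gaussian(gray, sigma=params.gaussian_sigma, preserve_range=True)
    if np.ptp(smooth) < 1e-9:
        warnings.warn("constant-intensity image: Otsu threshold undefined, "
                      "returning empty tissue mask")
        return np.zeros(gray.shape, dtype=bool)
    thresh = threshold_otsu(smooth)
    mask = smooth < thresh          # darker class = tissue
    selem = disk(params.morph_radius)
    mask = dilation(mask, selem)
    mask = erosion(mask, selem)
    return mask
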