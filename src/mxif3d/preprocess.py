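"""Illumination correction, intensity normalization and AF tissue masking.

The autofluorescence (AF) channel is imaged before any staining round, so it
is independent of biomarker signal and serves two roles downstream: a tissue
mask that focuses registration on the specimen and suppresses background
artefacts, and the registration substrate itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from .sections import Section

__all__ = [
    "Section",
    "IlluminationModel",
    "correct_illumination",
    "normalize_zmuv",
    "compute_af_mask",
]


@dataclass
class IlluminationModel:
    """Flat-field model: a background (blank-glass) frame acquired at a known
    exposure, plus a smooth multiplicative non-uniformity field with unit mean."""

    background_frame: np.ndarray
    background_exposure: float
    nonuniformity_field: np.ndarray

    def __post_init__(self) -> None:
        self.background_frame = np.asarray(self.background_frame, dtype=float)
        self.nonuniformity_field = np.asarray(self.nonuniformity_field, dtype=float)
        if self.background_exposure <= 0:
            raise ValueError("background_exposure must be positive")
        if np.any(self.nonuniformity_field <= 0):
            raise ValueError("nonuniformity_field must be positive everywhere")
        if abs(self.nonuniformity_field.mean() - 1.0) > 1e-6:
            raise ValueError("nonuniformity_field must have unit mean")


def correct_illumination(
    image: np.ndarray, model: IlluminationModel, exposure: float
) -> np.ndarray:
    """Subtract the exposure-scaled background frame, divide out the
    non-uniformity field, and clip at zero.

    ``out = clip((image - background * exposure / background_exposure) / field, 0)``
    """
    image = np.asarray(image, dtype=float)
    if exposure <= 0:
        raise ValueError("exposure must be positive")
    if image.shape != model.background_frame.shape or image.shape != model.nonuniformity_field.shape:
        raise ValueError("image and illumination model shapes do not match")
    scaled_bg = model.background_frame * (exposure / model.background_exposure)
    return np.clip((image - scaled_bg) / model.nonuniformity_field, 0.0, None)


def normalize_zmuv(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    return_params: bool = False,
) -> np.ndarray | tuple[np.ndarray, float, float]:
    """Normalize to zero mean, unit standard deviation inside ``mask``.

    The same affine map is applied to out-of-mask pixels, so the transform is
    monotone and invertible (``x = out * sd + mean``). With ``return_params``
    the fitted ``(mean, sd)`` are returned for denormalization.
    """
    image = np.asarray(image, dtype=float)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != image.shape:
            raise ValueError("mask shape does not match image")
        vals = image[mask]
    else:
        vals = image.ravel()
    if vals.size < 2 or np.ptp(vals) == 0:
        raise ValueError("degenerate intensity distribution")
    mean = float(vals.mean())
    sd = float(vals.std())
    out = (image - mean) / sd
    if return_params:
        return out, mean, sd
    return out


def compute_af_mask(af_image: np.ndarray, closing_radius_px: int = 5) -> np.ndarray:
    """Tissue mask from an AF image.

    Otsu threshold (256 bins over the observed range, maximizing
    between-class variance), morphological closing with a disk, then the
    largest 8-connected foreground component. The threshold adapts to each
    section's AF distribution, which is what makes the mask robust to
    section-to-section AF variation.
    """
    af_image = np.asarray(af_image, dtype=float)
    if np.ptp(af_image) == 0:
        raise ValueError("constant AF image: cannot threshold")
    thresh = threshold_otsu(af_image, nbins=256)
    fg = af_image > thresh
    if not fg.any():
        raise ValueError("no tissue found")
    if closing_radius_px > 0:
        fg = ndi.binary_closing(fg, structure=disk(closing_radius_px))
    labels, n = ndi.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise ValueError("no tissue found")
    counts = np.bincount(labels.ravel())[1:]
    best = np.flatnonzero(counts == counts.max()) + 1
    if best.size == 1:
        keep = best[0]
    else:
        # tie: component whose first pixel in raster order comes first
        keep = min(best, key=lambda lab: np.flatnonzero(labels.ravel() == lab)[0])
    return labels == keep
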