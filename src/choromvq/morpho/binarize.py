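"""ROI-restricted binarization of reconstructed microvessel images."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import remove_small_objects

from ..recon import HDMIImage

__all__ = ["BinaryVesselMask", "binarize"]


@dataclass
class BinaryVesselMask:
    """Binary vessel map restricted to a region of interest."""

    mask: np.ndarray   # (H, W) bool, subset of roi
    roi: np.ndarray    # (H, W) bool
    pixel_pitch_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.mask.shape != self.roi.shape:
            raise ValueError("mask and roi shapes differ")
        if np.any(self.mask & ~self.roi):
            raise ValueError("mask must be contained in the ROI")
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def binarize(
    image: HDMIImage | np.ndarray,
    roi: np.ndarray,
    method: str = "otsu",
    min_object_px: int = 4,
    *,
    quantile: float = 0.85,
    pixel_pitch_um: float | None = None,
) -> BinaryVesselMask:
    """Threshold a microvessel image inside an ROI.

    The threshold is computed from ROI pixels only: Otsu by default, or a
    fixed intensity quantile (``method='quantile'``). A constant ROI has no
    separable foreground and yields an empty mask. Connected components
    smaller than ``min_object_px`` are removed.
    """
    if isinstance(image, HDMIImage):
        intensity = image.intensity
        pitch = image.pixel_pitch_um
    else:
        intensity = np.asarray(image, dtype=float)
        pitch = pixel_pitch_um if pixel_pitch_um is not None else 1.0
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != intensity.shape:
        raise ValueError("ROI shape must match the image")
    if not roi.any():
        raise ValueError("ROI is empty")
    if not np.isfinite(intensity[roi]).all():
        raise ValueError("image contains non-finite values inside the ROI")

    if method not in ("otsu", "quantile"):
        raise ValueError(f"unknown binarization method {method!r}")
    vals = intensity[roi]
    if np.ptp(vals) == 0:  # degenerate: nothing to separate
        mask = np.zeros_like(roi)
        return BinaryVesselMask(mask, roi, pitch)

    if method == "otsu":
        thr = threshold_otsu(vals)
    else:
        if not 0.0 < quantile < 1.0:
            raise ValueError("quantile must lie in (0, 1)")
        thr = np.quantile(vals, quantile)

    mask = (intensity > thr) & roi
    if min_object_px > 1:
        mask = remove_small_objects(mask, max_size=min_object_px - 1, connectivity=2)
    return BinaryVesselMask(mask, roi, pitch)
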