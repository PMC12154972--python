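"""Amorphous-ECM area fraction from H&E-like light-microscopy images.

The statistic mirrors the study's light-microscopy readout: within a
dermal region of interest, pixels brighter than a threshold are counted
as unstained (amorphous ground substance) and the rest as eosin-stained
(fibrillar, mainly collagen); the result is expressed as the unstained
percentage of the total dermal connective tissue. Both counts are kept
so the unstained/stained ratio is also recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .images import CalibratedImage, RegionMask

__all__ = [
    "AmorphousResult",
    "full_roi",
    "select_threshold",
    "classify_amorphous",
    "amorphous_percentage",
]


@dataclass(frozen=True)
class AmorphousResult:
    unstained_count: int
    stained_count: int
    amorphous_pct: float
    threshold_used: float

    @property
    def unstained_over_stained(self) -> float:
        """The alternative ratio expression (unstained / stained)."""
        if self.stained_count == 0:
            return float("inf")
        return self.unstained_count / self.stained_count


def full_roi(image: CalibratedImage, layer_label: str = "none") -> RegionMask:
    """ROI covering the whole image (synthetic fields are all-dermis)."""
    return RegionMask(np.ones(image.shape, dtype=bool), layer_label)


def _check_roi(image: CalibratedImage, roi: RegionMask) -> None:
    if roi.member.shape != image.shape:
        raise ValueError("ROI shape does not match image")
    if roi.n_pixels == 0:
        raise ValueError("empty ROI")


def select_threshold(
    image: CalibratedImage,
    roi: RegionMask,
    method: str = "otsu",
    value: float | None = None,
) -> float:
    """Pick the stained/unstained intensity threshold for an ROI.

    ``method="fixed"`` returns `value` unchanged (the expert-defined
    threshold supplied in config); ``method="otsu"`` maximizes
    between-class variance over the ROI histogram.
    """
    _check_roi(image, roi)
    if method == "fixed":
        if value is None or not 0.0 < value < 1.0:
            raise ValueError("fixed threshold requires a value in (0, 1)")
        return float(value)
    if method != "otsu":
        raise ValueError(f"unknown threshold method {method!r}")
    pix = image.intensities[roi.member]
    if np.ptp(pix) == 0:
        raise ValueError("constant-intensity ROI: no separable classes for Otsu")
    return float(threshold_otsu(pix))


def classify_amorphous(
    image: CalibratedImage, roi: RegionMask, threshold: float
) -> RegionMask:
    """Mask of unstained (amorphous) pixels: in-ROI intensity > threshold."""
    _check_roi(image, roi)
    # 1.0 is admitted as the degenerate "nothing above" threshold
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    return RegionMask(roi.member & (image.intensities > threshold), roi.layer_label)


def amorphous_percentage(
    image: CalibratedImage, roi: RegionMask, threshold: float
) -> AmorphousResult:
    """Unstained and stained pixel counts plus the amorphous percentage
    of the ROI (100 * unstained / (unstained + stained))."""
    mask = classify_amorphous(image, roi, threshold)
    unstained = mask.n_pixels
    total = roi.n_pixels
    return AmorphousResult(
        unstained_count=unstained,
        stained_count=total - unstained,
        amorphous_pct=100.0 * unstained / total,
        threshold_used=float(threshold),
    )
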