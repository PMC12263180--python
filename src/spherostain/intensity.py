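"""Background-corrected intensity statistics per spheroid and channel.

Two statistics are computed from the thresholded channel:

*mean intensity* — mean of the positive (above-threshold) pixels minus the
mean background.  The sign convention is signal minus background, so a
negative value indicates that the background is brighter than the signal
inside the spheroid (e.g. an antibody that washed out poorly).

*total normalized intensity (TNI)* — total positive-pixel intensity,
background-corrected per positive pixel, divided by the spheroid slice
area::

    TNI = (sum(I_positive) - mean_background * n_positive) / spheroid_area

TNI is the appropriate statistic for punctate or heterogeneous stains
(Golgi puncta, junction networks) whose mean over positive pixels alone is
dominated by segmentation granularity.  The area denominator is in pixels
by default, giving TNI units of intensity per pixel of spheroid area; a
µm² denominator is available and flagged in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import SegmentationResult, estimate_background
from .synthgen import SpheroidImage


@dataclass
class IntensityStats:
    channel: str
    mean_intensity: float  #: may be negative (background exceeds signal)
    total_normalized_intensity: float
    positive_pixel_count: int
    mean_background: float
    spheroid_area_px: int
    spheroid_area_um2: float
    area_unit: str = "px"  #: denominator used for TNI


def mean_intensity(channel: np.ndarray, positive_mask: np.ndarray, mean_background: float) -> float:
    """Mean positive-pixel intensity minus mean background (may be negative)."""
    if not positive_mask.any():
        raise ValueError("positive mask is empty; mean intensity undefined")
    return float(channel[positive_mask].mean()) - float(mean_background)


def total_normalized_intensity(
    channel: np.ndarray,
    positive_mask: np.ndarray,
    mean_background: float,
    spheroid_area: float,
) -> float:
    """Background-corrected total positive intensity per unit spheroid area."""
    if spheroid_area <= 0:
        raise ValueError("spheroid_area must be positive")
    n_pos = int(positive_mask.sum())
    if n_pos == 0:
        return 0.0
    total = float(channel[positive_mask].sum(dtype=np.float64))
    return (total - float(mean_background) * n_pos) / float(spheroid_area)


def compute_stats(
    image: SpheroidImage,
    channel: str,
    seg: SegmentationResult,
    background_mode: str = "inverse",
    area_unit: str = "px",
) -> IntensityStats:
    """Both intensity statistics for one channel of one spheroid image."""
    if area_unit not in ("px", "um2"):
        raise ValueError("area_unit must be 'px' or 'um2'")
    bg = estimate_background(image, channel, seg, region_mode=background_mode)
    arr = image.channels[channel]
    pos = seg.positive_masks[channel]
    area = seg.area_px if area_unit == "px" else seg.area_um2
    return IntensityStats(
        channel=channel,
        mean_intensity=mean_intensity(arr, pos, bg),
        total_normalized_intensity=total_normalized_intensity(arr, pos, bg, area),
        positive_pixel_count=int(pos.sum()),
        mean_background=bg,
        spheroid_area_px=seg.area_px,
        spheroid_area_um2=seg.area_um2,
        area_unit=area_unit,
    )
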