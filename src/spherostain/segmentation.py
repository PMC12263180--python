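"""Thresholding, background estimation and spheroid delineation.

The analysis convention is: one scalar threshold per channel, determined
once for an entire image set and applied uniformly to every image in it,
so intensity statistics are comparable across conditions.  Sub-threshold
pixels (the "inverse threshold" region) provide the mean background
estimate; the spheroid region is delineated from the nuclear channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk

from .errors import DegenerateHistogramError, EmptyRegionError, EmptySpheroidError
from .synthgen import SpheroidImage

#: background estimation modes
BACKGROUND_MODES = ("inverse", "matrix_only", "cytoplasm")


@dataclass
class SegmentationResult:
    """Per-image segmentation: channel masks plus spheroid geometry."""

    positive_masks: dict[str, np.ndarray] = field(default_factory=dict)
    background_masks: dict[str, np.ndarray] = field(default_factory=dict)
    spheroid_mask: np.ndarray | None = None
    center: tuple[float, float] | None = None  #: (x, y) µm
    area_px: int = 0
    area_um2: float = 0.0
    equivalent_diameter_um: float = 0.0
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def radius_um(self) -> float:
        return self.equivalent_diameter_um / 2.0


def determine_thresholds(
    images: list[SpheroidImage],
    mode: str = "auto",
    fixed: dict[str, float] | None = None,
) -> dict[str, float]:
    """One scalar threshold per channel, shared by the whole image set.

    ``fixed`` mode passes through the configured per-channel values.
    ``auto`` mode applies Otsu's criterion to the histogram pooled over
    every image in the set, which is deterministic and guarantees the
    same threshold is applied to all images.
    """
    if not images:
        raise ValueError("need at least one image")
    channels = images[0].channel_names
    if mode == "fixed":
        if fixed is None:
            raise ValueError("fixed mode requires configured threshold values")
        missing = [c for c in channels if c not in fixed]
        if missing:
            raise ValueError(f"fixed thresholds missing for channels: {missing}")
        return {c: float(fixed[c]) for c in channels}
    if mode != "auto":
        raise ValueError(f"unknown threshold mode {mode!r}")

    out: dict[str, float] = {}
    for c in channels:
        counts = np.zeros(65536, dtype=np.int64)
        for img in images:
            counts += np.bincount(img.channels[c].ravel(), minlength=65536)
        if np.count_nonzero(counts) < 2:
            raise DegenerateHistogramError(
                f"channel {c!r} has constant intensity; cannot auto-threshold"
            )
        t = float(threshold_otsu(hist=(counts, np.arange(65536))))
        # Otsu's foreground is "> t" on integer data; our positive masks use
        # ">= threshold", so place the threshold half a level above the bin
        out[c] = t + 0.5
    return out


def apply_threshold(channel: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Split a channel into positive (>= threshold) and background (< threshold).

    The two masks are disjoint and together cover the whole field.
    """
    positive = channel >= threshold
    return positive, ~positive


def estimate_background(
    image: SpheroidImage,
    channel: str,
    seg: SegmentationResult,
    region_mode: str = "inverse",
) -> float:
    """Mean background intensity of one channel.

    ``inverse``
        mean over all sub-threshold pixels of the field;
    ``matrix_only``
        sub-threshold pixels outside the spheroid mask (surrounding gel);
    ``cytoplasm``
        sub-threshold pixels inside the spheroid mask, for antibodies with
        non-specific cytoplasmic carryover where the matrix is not the
        relevant background.
    """
    if region_mode not in BACKGROUND_MODES:
        raise ValueError(f"unknown background mode {region_mode!r}")
    bg = seg.background_masks[channel]
    if region_mode != "inverse":
        if seg.spheroid_mask is None:
            raise ValueError(f"mode {region_mode!r} requires a spheroid mask")
        bg = bg & ~seg.spheroid_mask if region_mode == "matrix_only" else bg & seg.spheroid_mask
    if not bg.any():
        raise EmptyRegionError(f"background region empty in mode {region_mode!r}")
    return float(image.channels[channel][bg].mean())


def find_spheroid(
    image: SpheroidImage,
    nuclear_threshold: float,
    nuclear_channel: str = "dapi",
    closing_um: float = 5.0,
) -> SegmentationResult:
    """Delineate the spheroid from the nuclear channel.

    The positive nuclear mask is morphologically closed (disk of radius
    ``closing_um``, bridging the gaps between neighbouring nuclei),
    hole-filled, and the largest connected component is kept.  The
    centroid, pixel/µm² area and equivalent circular diameter of that
    component describe the spheroid slice.
    """
    if nuclear_channel not in image.channels:
        raise ValueError(f"nuclear channel {nuclear_channel!r} not in image")
    px = image.pixel_size
    positive, _ = apply_threshold(image.channels[nuclear_channel], nuclear_threshold)
    if not positive.any():
        raise EmptySpheroidError("no positive nuclear pixels; cannot delineate spheroid")
    r_px = max(1, int(round(closing_um / px)))
    closed = closing(positive, footprint=disk(r_px))
    filled = ndimage.binary_fill_holes(closed)
    labels = label(filled)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    rows, cols = np.nonzero(mask)
    center = (float(cols.mean()) * px, float(rows.mean()) * px)  # (x, y) µm
    area_px = int(mask.sum())
    area_um2 = area_px * px * px
    eq_diam = 2.0 * np.sqrt(area_um2 / np.pi)
    return SegmentationResult(
        spheroid_mask=mask,
        center=center,
        area_px=area_px,
        area_um2=area_um2,
        equivalent_diameter_um=float(eq_diam),
    )


def segment_image(
    image: SpheroidImage,
    thresholds: dict[str, float],
    nuclear_channel: str = "dapi",
    closing_um: float = 5.0,
) -> SegmentationResult:
    """Full per-image segmentation: channel masks + spheroid geometry."""
    seg = find_spheroid(
        image, thresholds[nuclear_channel], nuclear_channel=nuclear_channel, closing_um=closing_um
    )
    seg.thresholds = dict(thresholds)
    for c in image.channel_names:
        if c not in thresholds:
            continue
        pos, bg = apply_threshold(image.channels[c], thresholds[c])
        seg.positive_masks[c] = pos
        seg.background_masks[c] = bg
    return seg


def select_center_slice(
    z_top: float,
    z_bottom: float,
    stack: np.ndarray,
    z_positions: np.ndarray | list[float],
) -> tuple[np.ndarray, int, float]:
    """Pick the slice at the spheroid's mid-depth.

    ``z_top`` and ``z_bottom`` are the recorded axial positions of the
    spheroid's top and bottom; the slice of ``stack`` whose z position is
    nearest to their midpoint is the center slice (ties break toward the
    lower index).  Also returns the overall spheroid diameter
    ``|z_bottom - z_top|``.
    """
    if z_top == z_bottom:
        raise ValueError("z_top and z_bottom must differ")
    z = np.asarray(z_positions, dtype=float)
    if len(z) != len(stack):
        raise ValueError("z_positions must match the stack length")
    mid = (z_top + z_bottom) / 2.0
    if mid < z.min() or mid > z.max():
        raise ValueError(f"mid-depth {mid:g} lies outside the stack range")
    i = int(np.argmin(np.abs(z - mid)))
    return stack[i], i, float(abs(z_bottom - z_top))
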