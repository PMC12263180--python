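"""Radial stain-penetration depth from half-maximum line profiles.

The depth-penetration statistic: cast evenly angled radial line profiles
from the spheroid perimeter toward the center, pool the samples within a
thin rim band into one perimeter reference intensity, and record for each
line the first depth at which the (lightly smoothed) profile falls below
half that reference.  Lines that never fall below half-maximum are flagged
*complete* and contribute the full radius to the average, so the mean is
unbiased as penetration approaches completeness.  The fractional depth is
the mean depth normalized by the spheroid radius, so 1.0 means the stain
reached the center ("complete penetration").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates, uniform_filter1d

from .errors import UnstainedPerimeterError
from .segmentation import SegmentationResult
from .synthgen import SpheroidImage


@dataclass
class RadialProfileSet:
    """Line profiles of one channel of one spheroid.

    ``depths_um`` runs from 0 (perimeter) to the radius (center) and is
    shared by all lines; ``profiles`` is (n_lines, n_samples).
    """

    depths_um: np.ndarray
    profiles: np.ndarray
    n_lines: int
    sampling_step_um: float
    radius_um: float


@dataclass
class PenetrationResult:
    mean_depth_um: float
    sd_depth_um: float
    fractional_depth: float  #: mean depth / radius, clipped to [0, 1]
    complete: bool  #: every line stayed above half-maximum to the center
    n_lines_used: int
    n_lines_complete: int
    rim_mean: float


def extract_profiles(
    channel: np.ndarray,
    center_um: tuple[float, float],
    radius_um: float,
    pixel_size: float,
    n_lines: int = 36,
    step_um: float | None = None,
) -> RadialProfileSet:
    """Sample evenly angled radial rays from the perimeter to the center.

    Intensities are sampled by bilinear interpolation every ``step_um``
    (default: one pixel); depth is measured inward from the perimeter.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if n_lines < 4:
        raise ValueError("need at least 4 line profiles")
    step = pixel_size if step_um is None else float(step_um)
    if step <= 0:
        raise ValueError("step_um must be positive")
    depths = np.arange(0.0, radius_um + step / 2, step)
    if depths[-1] < radius_um - 1e-9:
        depths = np.append(depths, radius_um)
    angles = 2 * np.pi * np.arange(n_lines) / n_lines
    r = radius_um - depths  # µm from center, per sample
    cx, cy = center_um
    x = cx + np.outer(np.cos(angles), r)
    y = cy + np.outer(np.sin(angles), r)
    rows = y / pixel_size
    cols = x / pixel_size
    nr, nc = channel.shape
    if rows.min() < 0 or cols.min() < 0 or rows.max() > nr - 1 or cols.max() > nc - 1:
        raise ValueError("a radial line leaves the imaged field; check center/radius")
    profiles = map_coordinates(
        channel.astype(float), [rows.ravel(), cols.ravel()], order=1
    ).reshape(n_lines, depths.size)
    return RadialProfileSet(
        depths_um=depths,
        profiles=profiles,
        n_lines=n_lines,
        sampling_step_um=step,
        radius_um=radius_um,
    )


def rim_reference(profile_set: RadialProfileSet, rim_band_um: float = 5.0) -> float:
    """Mean perimeter intensity, pooled over all lines of the spheroid.

    All samples with depth <= ``rim_band_um`` enter one pooled mean: the
    half-maximum reference is a single per-spheroid value, not per-line.
    """
    if rim_band_um <= 0 or rim_band_um > profile_set.radius_um:
        raise ValueError("rim_band_um must be in (0, radius]")
    if rim_band_um < profile_set.sampling_step_um:
        raise ValueError("rim_band_um is smaller than the sampling step; empty rim band")
    sel = profile_set.depths_um <= rim_band_um + 1e-9
    return float(profile_set.profiles[:, sel].mean())


def half_max_depth(
    depths_um: np.ndarray,
    intensities: np.ndarray,
    rim_mean: float,
    smoothing_window: int = 3,
) -> tuple[float | None, bool]:
    """First depth where the smoothed profile falls below half the rim mean.

    The profile is smoothed with a centered moving average of
    ``smoothing_window`` samples; the crossing depth is linearly
    interpolated between the bracketing samples.  The search looks for a
    *downward* crossing: samples right at the perimeter can dip below
    threshold purely from partial-volume mixing with the surrounding
    matrix, so any leading below-threshold run is skipped and the depth
    recorded is where the profile first decreases through half-maximum.
    Returns ``(depth, False)``, or ``(None, True)`` when the profile never
    falls below half-maximum (complete penetration along this line).
    """
    if rim_mean <= 0:
        raise UnstainedPerimeterError("rim mean intensity is non-positive")
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    vals = np.asarray(intensities, dtype=float)
    if smoothing_window > 1:
        vals = uniform_filter1d(vals, size=smoothing_window, mode="nearest")
    thresh = 0.5 * rim_mean
    above = vals >= thresh
    if not above.any():
        # never above half-maximum beyond the perimeter: no penetration
        return float(depths_um[0]), False
    start = int(np.argmax(above))
    below = vals[start:] < thresh
    if not below.any():
        return None, True
    i = start + int(np.argmax(below))
    frac = (vals[i - 1] - thresh) / (vals[i - 1] - vals[i])
    return float(depths_um[i - 1] + frac * (depths_um[i] - depths_um[i - 1])), False


def summarize_penetration(
    profile_set: RadialProfileSet,
    rim_mean: float,
    radius_um: float | None = None,
    smoothing_window: int = 3,
) -> PenetrationResult:
    """Average per-line half-max depths into the spheroid's statistic.

    Complete lines (never below half-maximum) contribute the full radius.
    ``fractional_depth`` is the mean depth over the radius, clipped to
    [0, 1]; the spheroid is *complete* when every line is complete.
    """
    R = profile_set.radius_um if radius_um is None else float(radius_um)
    depths = []
    n_complete = 0
    for line in profile_set.profiles:
        d, complete = half_max_depth(
            profile_set.depths_um, line, rim_mean, smoothing_window=smoothing_window
        )
        if complete:
            n_complete += 1
            depths.append(R)
        else:
            depths.append(d)
    if len(depths) < 4:
        raise ValueError("fewer than 4 usable line profiles")
    depths = np.asarray(depths)
    mean = float(depths.mean())
    sd = float(depths.std(ddof=1)) if len(depths) > 1 else 0.0
    return PenetrationResult(
        mean_depth_um=mean,
        sd_depth_um=sd,
        fractional_depth=float(min(1.0, mean / R)),
        complete=n_complete == len(depths),
        n_lines_used=len(depths),
        n_lines_complete=n_complete,
        rim_mean=rim_mean,
    )


def measure_penetration(
    image: SpheroidImage,
    channel: str,
    center_um: tuple[float, float] | None = None,
    radius_um: float | None = None,
    seg: SegmentationResult | None = None,
    n_lines: int = 36,
    rim_band_um: float = 5.0,
    smoothing_window: int = 3,
    step_um: float | None = None,
) -> PenetrationResult:
    """End-to-end penetration measurement for one channel of one image.

    Geometry (center, radius) may be given directly or taken from a
    :class:`SegmentationResult`.
    """
    if center_um is None or radius_um is None:
        if seg is None or seg.center is None:
            raise ValueError("provide center/radius or a segmentation result")
        center_um = seg.center if center_um is None else center_um
        radius_um = seg.radius_um if radius_um is None else radius_um
    pset = extract_profiles(
        image.channels[channel], center_um, radius_um, image.pixel_size,
        n_lines=n_lines, step_um=step_um,
    )
    rim = rim_reference(pset, rim_band_um=rim_band_um)
    return summarize_penetration(pset, rim, smoothing_window=smoothing_window)
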