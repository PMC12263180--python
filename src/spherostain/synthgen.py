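"""Synthetic confocal images of immunostained, matrix-embedded spheroids.

This module emulates center-slice confocal images of multicellular spheroids
embedded in thick hydrogels (collagen or basement-membrane matrix) and
immunostained for four markers:

``dapi``
    nuclear DNA stain — filled disks at each cell nucleus;
``lamin``
    nuclear-envelope marker (lamin B1) — thin annuli around each nucleus;
``gm130``
    Golgi-associated marker — small puncta offset from each nucleus;
``bcatenin``
    cell–cell junction marker (β-catenin) — ridges along the boundaries
    between neighbouring cells, superimposed on a dimmer diffuse
    cytoplasmic pool.

Antibody/dye penetration into the spheroid is modeled as a radial staining
front that advances inward from the spheroid surface at a constant velocity
``front_velocity`` (µm/min), so the front depth after ``staining_time``
minutes is ``v·t`` (capped at the spheroid radius).  Stained structures
deeper than the front carry no signal; an optional complementary-error-
function ramp of scale ``front_width`` softens the front.  Residual stain in
the surrounding matrix (incomplete washout) is modeled as a uniform matrix
background, optics as a Gaussian point-spread blur, and detection as
Poisson photon noise plus additive Gaussian read noise.

Every image comes with a :class:`GroundTruth` record (cell positions,
spheroid center/radius, true per-channel front depth) so that the analysis
pipeline's recovery of the staining front can be checked against a known
answer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from scipy.special import erfc

from .errors import EmptySpheroidError

#: channel names, in storage order
CHANNELS = ("dapi", "lamin", "gm130", "bcatenin")

# Fixed stain-geometry constants (µm).  These are documented rendering
# choices, not fit to any data: a ~1 µm nuclear-envelope ring, sub-µm Golgi
# puncta and ~1 µm junctional ridges are typical apparent widths at
# confocal resolution.
ANNULUS_WIDTH_UM = 1.0
PUNCTA_RADIUS_UM = 0.8
RIDGE_WIDTH_UM = 1.0
#: diffuse cytoplasmic β-catenin pool, as a fraction of the junctional
#: ridge amplitude.  β-catenin is membrane-associated but maintains a
#: cytoplasmic pool, so the junction channel is never zero inside a
#: stained cell.
CYTOPLASM_FRACTION = 0.3

# Two-layer hydrogel geometry driving the embedding model: mean (± SD)
# thickness of the partially polymerized bottom collagen layer and of the
# spheroid-bearing top layer, in µm.  Their sum (~800 µm) is the total gel
# thickness through which stains must diffuse.
BOTTOM_LAYER_THICKNESS_UM = 197.5
BOTTOM_LAYER_THICKNESS_SD_UM = 51.4
TOP_LAYER_THICKNESS_UM = 607.7
TOP_LAYER_THICKNESS_SD_UM = 16.9


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of one simulated spheroid image.

    Defaults describe a densely packed MCF10A-like spheroid (~200 µm
    diameter) whose staining front reaches the center after ~110 min
    (velocity 0.91 µm/min).  See :func:`mcf7_params` for the loosely
    packed, faster-staining preset.
    """

    spheroid_diameter: float = 200.0  #: µm
    cell_min_spacing: float = 8.0  #: µm; minimum distance between cell centers
    nucleus_radius: float = 3.0  #: µm
    front_velocity: float = 0.91  #: µm/min; staining front advance speed
    staining_time: float = 120.0  #: min
    front_width: float = 0.0  #: µm; 0 = sharp front, >0 = erfc ramp scale
    rim_intensity: float = 3000.0  #: peak stain amplitude (detector units)
    matrix_background_fraction: float = 0.1  #: residual matrix stain, in [0, 1]
    psf_sigma: float = 0.5  #: µm; Gaussian PSF sigma, 0 disables blur
    poisson_scale: float = 1.0  #: photons per intensity unit; 0 disables shot noise
    read_noise_sd: float = 20.0  #: additive Gaussian noise SD; 0 disables
    pixel_size: float = 0.5  #: µm / pixel
    field_size: int = 1024  #: pixels per side
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spheroid_diameter <= 0:
            raise ValueError("spheroid_diameter must be positive")
        if self.spheroid_diameter >= self.field_size * self.pixel_size:
            raise ValueError(
                "spheroid_diameter must be smaller than the imaged field "
                f"({self.field_size * self.pixel_size:g} µm)"
            )
        if self.cell_min_spacing <= 0 or self.nucleus_radius <= 0:
            raise ValueError("cell_min_spacing and nucleus_radius must be positive")
        if self.front_velocity < 0 or self.staining_time < 0:
            raise ValueError("front_velocity and staining_time must be non-negative")
        if not 0.0 <= self.matrix_background_fraction <= 1.0:
            raise ValueError("matrix_background_fraction must lie in [0, 1]")
        if self.front_width < 0 or self.psf_sigma < 0:
            raise ValueError("front_width and psf_sigma must be non-negative")
        if self.poisson_scale < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.pixel_size <= 0 or self.field_size < 8:
            raise ValueError("pixel_size must be positive and field_size >= 8")

    @property
    def radius(self) -> float:
        return self.spheroid_diameter / 2.0

    @property
    def front_depth(self) -> float:
        """Nominal front depth v·t (µm), not capped at the radius."""
        return self.front_velocity * self.staining_time


def mcf10a_params(**overrides) -> SimulationParams:
    """Densely packed ~200 µm spheroid; full staining takes ~110 min."""
    return SimulationParams(**overrides)


def mcf7_params(**overrides) -> SimulationParams:
    """Loosely packed ~180 µm cancer spheroid.

    Lower junction-protein expression gives wider cell spacing and a
    weaker diffusion barrier, so the staining front moves ~2.5× faster
    and the spheroid stains completely in ~40 min.
    """
    defaults = dict(
        spheroid_diameter=180.0,
        cell_min_spacing=11.0,
        front_velocity=2.25,
        staining_time=40.0,
    )
    defaults.update(overrides)
    return SimulationParams(**defaults)


@dataclass
class GroundTruth:
    """Generator-side record of what was rendered (the recovery oracle)."""

    center: tuple[float, float]  #: (x, y) µm from the top-left pixel center
    radius: float  #: µm
    cell_centers: np.ndarray  #: (n, 2) array of (x, y) µm
    true_front_depth: dict[str, float]  #: µm per channel, capped at radius
    spheroid_mask: np.ndarray  #: boolean grid


@dataclass
class SpheroidImage:
    """Multi-channel 2-D center-slice image; the unit of analysis.

    Channels are stored row-major, origin at the top-left pixel,
    0-based indexing, 16-bit intensity range.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float  #: µm / pixel

    def __post_init__(self) -> None:
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def _rng(seed: int, stream: int) -> np.random.Generator:
    # independent deterministic substreams per (seed, purpose)
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def generate_geometry(params: SimulationParams) -> GroundTruth:
    """Place cell centers inside the spheroid disk by blue-noise sampling.

    Seeded dart throwing: candidate points are drawn uniformly in the disk
    and accepted when at least ``cell_min_spacing`` from every accepted
    point.  The number of attempts scales with the expected packing so the
    disk saturates; the result is deterministic for a fixed seed.
    """
    R = params.radius
    if params.cell_min_spacing > params.spheroid_diameter:
        raise EmptySpheroidError(
            f"cell_min_spacing {params.cell_min_spacing:g} µm exceeds the "
            f"spheroid diameter {params.spheroid_diameter:g} µm"
        )
    rng = _rng(params.seed, 0)
    n_attempts = int(max(200, 20 * (params.spheroid_diameter / params.cell_min_spacing) ** 2))
    cx = cy = (params.field_size - 1) / 2.0 * params.pixel_size
    accepted: list[np.ndarray] = []
    pts = np.empty((0, 2))
    min_sq = params.cell_min_spacing**2
    # draw all candidates up front so the random stream does not depend on
    # the acceptance pattern
    u = rng.random(n_attempts)
    theta = rng.random(n_attempts) * 2 * np.pi
    rr = R * np.sqrt(u)
    cand = np.column_stack([cx + rr * np.cos(theta), cy + rr * np.sin(theta)])
    for p in cand:
        if pts.shape[0] == 0 or np.min(np.sum((pts - p) ** 2, axis=1)) >= min_sq:
            accepted.append(p)
            pts = np.asarray(accepted)
    if pts.shape[0] == 0:
        raise EmptySpheroidError("no cell could be placed in the spheroid")

    idx = np.arange(params.field_size) * params.pixel_size
    X, Y = np.meshgrid(idx, idx)
    mask = (X - cx) ** 2 + (Y - cy) ** 2 <= R**2
    depth = min(params.front_depth, R)
    return GroundTruth(
        center=(cx, cy),
        radius=R,
        cell_centers=pts,
        true_front_depth={c: depth for c in CHANNELS},
        spheroid_mask=mask,
    )


def penetration_profile(depth_from_surface, params: SimulationParams):
    """Fraction of full stain intensity at a given depth below the surface.

    Sharp mode (``front_width == 0``) is a unit step at the front depth
    ``v·t``; smooth mode is a complementary-error-function ramp centered at
    the front with scale ``front_width``.  Monotonically non-increasing in
    depth; accepts scalars or arrays.
    """
    depth = np.asarray(depth_from_surface, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth_from_surface must be non-negative")
    fd = params.front_depth
    if params.front_width == 0:
        out = (depth <= fd).astype(float)
    else:
        out = 0.5 * erfc((depth - fd) / (params.front_width * np.sqrt(2.0)))
    if np.isscalar(depth_from_surface):
        return float(out)
    return out


def render(geometry: GroundTruth, params: SimulationParams) -> SpheroidImage:
    """Render the four stain channels for a given cell geometry.

    Stain structures exist only inside the spheroid disk and are
    attenuated by :func:`penetration_profile` of their radial depth from
    the spheroid surface.  Matrix pixels (outside the disk) receive
    ``rim_intensity × matrix_background_fraction`` in every channel.
    The image is then blurred (Gaussian PSF), shot noise and read noise
    are applied, and the result is clipped and quantized to 16 bits.
    """
    n = params.field_size
    px = params.pixel_size
    cx, cy = geometry.center
    R = geometry.radius
    idx = np.arange(n) * px
    X, Y = np.meshgrid(idx, idx)
    r_grid = np.hypot(X - cx, Y - cy)
    inside = r_grid <= R
    depth_grid = np.maximum(R - r_grid, 0.0)
    attenuation = penetration_profile(depth_grid, params)

    pix_in = np.column_stack([X[inside], Y[inside]])
    tree = cKDTree(geometry.cell_centers)
    k = min(2, len(geometry.cell_centers))
    d, _ = tree.query(pix_in, k=k)
    d = np.atleast_2d(d.T).T if d.ndim == 1 else d
    d1 = d[:, 0]
    gap = (d[:, 1] - d1) if k == 2 else np.full_like(d1, np.inf)

    A = params.rim_intensity
    structures = {
        "dapi": (d1 <= params.nucleus_radius).astype(float),
        "lamin": (
            (d1 > params.nucleus_radius)
            & (d1 <= params.nucleus_radius + ANNULUS_WIDTH_UM)
        ).astype(float),
    }
    # Golgi: one punctum per cell, offset from the nucleus in a random
    # direction (deterministic substream of the image seed)
    rng_g = _rng(params.seed, 1)
    ang = rng_g.random(len(geometry.cell_centers)) * 2 * np.pi
    off = params.nucleus_radius + PUNCTA_RADIUS_UM + 0.2
    golgi_centers = geometry.cell_centers + off * np.column_stack([np.cos(ang), np.sin(ang)])
    dg, _ = cKDTree(golgi_centers).query(pix_in, k=1)
    structures["gm130"] = (dg <= PUNCTA_RADIUS_UM).astype(float)
    # junction marker: Voronoi boundary ridges plus diffuse cytoplasmic pool
    structures["bcatenin"] = np.where(gap <= RIDGE_WIDTH_UM, 1.0, CYTOPLASM_FRACTION)

    matrix_level = A * params.matrix_background_fraction
    rng_noise = _rng(params.seed, 2)
    channels: dict[str, np.ndarray] = {}
    for name in CHANNELS:
        img = np.full((n, n), matrix_level, dtype=float)
        img[inside] = A * structures[name] * attenuation[inside]
        if params.psf_sigma > 0:
            img = gaussian_filter(img, params.psf_sigma / px)
        if params.poisson_scale > 0:
            img = rng_noise.poisson(np.clip(img, 0, None) * params.poisson_scale) / params.poisson_scale
        if params.read_noise_sd > 0:
            img = img + rng_noise.normal(0.0, params.read_noise_sd, img.shape)
        channels[name] = np.round(np.clip(img, 0, 65535)).astype(np.uint16)
    return SpheroidImage(channels=channels, pixel_size=px)


def simulate_spheroid(params: SimulationParams) -> tuple[SpheroidImage, GroundTruth]:
    """Geometry + rendering in one call."""
    geom = generate_geometry(params)
    return render(geom, params), geom


def simulate_timecourse(
    params_base: SimulationParams,
    times: list[float],
    n_per_time: int,
    seed: int,
) -> tuple[list[SpheroidImage], pd.DataFrame]:
    """Simulate a staining time course (replicate spheroids per time).

    Per-image seeds are derived deterministically from the master seed.
    Returns the images (ordered as the table rows) and a ground-truth
    table with one row per spheroid: id, staining time, center, radius
    and true per-channel front depth.
    """
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    if n_per_time < 1:
        raise ValueError("n_per_time must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(times) * n_per_time) >> 1
    images: list[SpheroidImage] = []
    rows: list[dict] = []
    i = 0
    for t in times:
        for rep in range(n_per_time):
            p = dataclasses.replace(params_base, staining_time=float(t), seed=int(child_seeds[i]))
            img, geom = simulate_spheroid(p)
            images.append(img)
            row = {
                "spheroid_id": f"t{t:g}_r{rep}",
                "time_min": float(t),
                "replicate": rep,
                "seed": int(child_seeds[i]),
                "center_x_um": geom.center[0],
                "center_y_um": geom.center[1],
                "radius_um": geom.radius,
                "n_cells": len(geom.cell_centers),
            }
            for c in CHANNELS:
                row[f"true_depth_{c}_um"] = geom.true_front_depth[c]
            rows.append(row)
            i += 1
    return images, pd.DataFrame(rows)
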