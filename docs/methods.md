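# Methods

## The measurement problem

Immunostaining of spheroids embedded in thick hydrogels is limited by
diffusion of the staining reagents through the gel and through the packed
cell mass. On a confocal slice through the spheroid center, this appears
as a stained rim of some radial thickness and an unstained (or weakly
stained) core; the rim thickness grows with staining time until the stain
reaches the center. The package quantifies this with two families of
statistics: a geometric one (how deep did the stain get?) and an
intensometric one (how much signal accumulated, relative to background?).

## Penetration depth

For each spheroid and channel, `n_lines` (default 36) evenly angled rays
are cast from the perimeter toward the center, sampled by bilinear
interpolation at one-pixel spacing. All samples within the rim band
(default 5 µm from the perimeter) are pooled — over all lines — into one
perimeter reference intensity per spheroid; per-line depth is where the
profile, smoothed by a centered moving average (default 3 samples), first
*decreases* below half that reference, linearly interpolated between the
bracketing samples.

Numerical conventions, chosen where the procedure is underdetermined:

- **Downward crossing.** The sample exactly at the perimeter mixes
  spheroid and matrix intensities (partial-volume at the disk edge) and
  can sit below threshold even on a fully stained rim, so any leading
  below-threshold run is skipped and the first genuine decrease through
  half-maximum is recorded. If a profile never rises above threshold at
  all, depth 0 is reported.
- **Complete lines.** Lines that never fall below half-maximum are fully
  penetrated and contribute the full radius to the mean; this keeps the
  average unbiased as staining approaches completeness. The spheroid is
  flagged complete when every line is complete.
- **Pooled rim.** One reference per spheroid (not per line), since the
  perimeter mean is a property of the spheroid's stained surface; per-line
  references would be noisy on punctate or network stains.
- **Fractional depth** is mean depth / radius, clipped to [0, 1]. Radius
  normalization (rather than diameter) is the only reading under which a
  ~100 µm deep front in a ~200 µm spheroid maps to "complete" (1.0).

On noiseless synthetic spheroids with sharp fronts, the pipeline recovers
front depths at 10–90 % of the radius to well within one pixel (0.5 µm at
the default pixel size); the test suite asserts this bound.

## Intensity statistics

One threshold per channel is determined for the entire image set — fixed
per-channel values, or Otsu's criterion on the histogram pooled over all
images (shifted half an intensity level so the `≥ threshold` positive mask
matches Otsu's foreground partition). Mean background comes from the
sub-threshold ("inverse") region: whole field by default, restricted to
outside the spheroid (`matrix_only`) or inside it (`cytoplasm`) when an
antibody's relevant background is matrix carryover or non-specific
cytoplasmic staining respectively.

*Mean intensity* is mean positive signal minus mean background, oriented
so that a stain dimmer than its background is negative. *Total normalized
intensity* is the background-corrected total positive intensity divided by
the spheroid slice area (in pixels by default, so TNI has units of
intensity per pixel of spheroid area; the µm² denominator is available and
flagged). TNI is homogeneous of degree 1 under joint scaling of image,
threshold and background, and is invariant to changes in sub-threshold
pixels; both properties are asserted in tests.

The spheroid region itself is delineated from the nuclear channel:
positive mask, morphological closing (disk radius 5 µm by default,
bridging inter-nuclear gaps), hole filling, largest connected component.
Between rim nuclei the resulting boundary scallops inward by a micron or
two, so the equivalent diameter slightly underestimates the true one
(≲ 2–3 % on 100–200 µm spheroids); analyses that need exact geometry
(recovery tests) take center/radius from the generator's ground-truth
table instead, which the file formats support end to end.

## Statistics

Time courses are fit by ordinary least squares of response on staining
time (not through the origin; an intercept absorbs lag and thresholding
offsets). R² is reported, and defined as 0 for a constant response. The
predicted completion time solves `intercept + slope·t = 1` on the
fractional response.

Two-group comparisons are gated by a two-sided F-test of variance equality
(doubled smaller tail; the statistic is reported as larger variance over
smaller) at the same α (default 0.05): Welch's two-tailed t-test when
rejected, otherwise the unpaired Student's t-test. Stars follow
\* p<0.05, ** p≤0.01, *** p≤0.001, **** p≤0.0001. No multiple-testing
correction is applied across channels — comparisons are reported
per channel, and users comparing many markers should correct externally.
Summaries are mean ± sample SD (n−1).

## The synthetic generator

The generator's defaults describe the study conditions the pipeline is
meant for:

| parameter | default | meaning |
|---|---|---|
| `spheroid_diameter` | 200 µm (MCF10A preset); 180 µm (MCF7) | center-slice disk diameter |
| `cell_min_spacing` | 8 µm (MCF10A); 11 µm (MCF7) | blue-noise packing distance |
| `nucleus_radius` | 3 µm | nuclear disk radius |
| `front_velocity` | 0.91 µm/min (MCF10A); 2.25 µm/min (MCF7) | staining-front advance |
| `staining_time` | 120 min (MCF10A); 40 min (MCF7) | primary staining duration |
| `front_width` | 0 µm | 0 = sharp front; >0 = erfc ramp scale |
| `rim_intensity` | 3000 | peak stain amplitude (16-bit detector units) |
| `matrix_background_fraction` | 0.1 | residual matrix stain / peak |
| `psf_sigma` | 0.5 µm | Gaussian PSF |
| `poisson_scale` | 1.0 | photons per intensity unit (0 = off) |
| `read_noise_sd` | 20 | additive Gaussian noise |
| `pixel_size`, `field_size` | 0.5 µm, 1024 px | a 512 µm field resolves a 200 µm spheroid |

Cell packing is seeded dart throwing (minimum-distance rejection) with a
pre-drawn candidate stream, so output is bit-identical for a fixed seed
and density is controlled by the single spacing knob. The MCF10A/MCF7
presets emulate densely vs loosely packed epithelial spheroids: wider
spacing means fewer diffusion barriers, hence the faster front. The
MCF10A velocity (0.91 µm/min) makes a 100 µm radius stain completely in
~110 min; the MCF7 velocity (2.25 µm/min) stains a 90 µm radius in
~40 min, matching the staining durations of the built-in protocols. The
intensity scale is arbitrary (real stains have none that transfers across
instruments), so `rim_intensity` is config-exposed.

Rendered structures: nuclear disks; 1 µm nuclear-envelope annuli; 0.8 µm
Golgi puncta offset from each nucleus in a seeded random direction; and a
junction network of 1 µm ridges along the Voronoi boundaries of the cell
packing. The junction channel additionally carries a diffuse cytoplasmic
pool at 30 % of ridge amplitude inside the spheroid — β-catenin-class
markers genuinely maintain a cytoplasmic fraction, and it is this pool
that makes radial line profiles of a network stain well-defined (a pure
ridge network is mostly empty along any single ray). All structures are
clipped to the spheroid disk and multiplied by the front profile of their
depth; matrix pixels get `rim_intensity × matrix_background_fraction`.
Blur, Poisson noise (variance = mean at `poisson_scale` 1, verified by a
Monte-Carlo test) and read noise are applied in that order, then the image
is clipped and quantized to 16 bits.

The two-layer embedding geometry (bottom collagen layer 197.5 ± 51.4 µm,
spheroid-bearing top layer 607.7 ± 16.9 µm, ~800 µm total) is recorded as
module constants; it documents the diffusion distances the protocols
contend with but is not rendered.

What the generator does **not** emulate — so what passing tests do not
show about real data: optical attenuation and scattering with depth,
refractive-index mismatch, chromatic misregistration, nuclear texture and
cell-shape irregularity, antibody binding kinetics beyond a constant-
velocity front, and any collagen-fiber (SHG) channel. Recovery results on
synthetic data bound algorithmic error only, not instrument effects.

## Problem sizes

The test suite runs small fields (192–512 px) and few replicates so the
full suite completes in well under a minute; the acceptance script uses
the full default field (1024 px) with 5 spheroids per time point at six
staining times, which it simulates and analyzes in under a minute on one
CPU. Seeds are fixed everywhere; identical parameters and seed give
bit-identical images and byte-identical result tables.

## Known limitations

- Spheroids are modeled as disks on the center slice; irregular or fused
  spheroids will bias the equivalent-radius normalization.
- The nuclear-channel delineation needs a stained rim at minimum; at very
  short staining times an incompletely closed nuclear ring can defeat
  hole-filling, which is why recovery analyses prefer recorded geometry.
- The half-max statistic assumes the perimeter is the brightest stained
  zone; stains that accumulate in the core (inside-out gradients) need a
  different reference.
- One threshold per set is a deliberate comparability constraint;
  per-image auto-thresholding would track illumination drift better but
  break cross-condition comparisons.
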