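# spherostain

Quantification of immunofluorescence staining in multicellular spheroids
embedded in thick hydrogel matrices (collagen, basement-membrane extract),
plus a synthetic confocal image generator with known staining ground truth.

Whole-mount immunostaining of gel-embedded spheroids is diffusion limited:
antibodies penetrate the matrix and the packed cell mass slowly, so the
staining front sits at some radial depth below the spheroid surface that
grows with staining time. This package implements the image analysis used
to quantify that process from center-slice confocal images, for anyone
comparing staining protocols (e.g. accelerated vs conventional benchtop
workflows) on 3-D culture models:

- **Half-maximum radial penetration depth.** Radial line profiles are cast
  from the spheroid perimeter toward the center; the depth where the
  (lightly smoothed) signal first drops below half the pooled perimeter
  mean is the penetration depth of that line, averaged over lines. The
  *fractional* depth is the mean depth over the spheroid radius
  (1.0 = complete penetration).
- **Background-corrected intensity statistics.** With one threshold per
  channel applied to the whole image set, the *mean intensity* is
  `mean(I | I ≥ t) − background` (negative when background dominates), and
  the *total normalized intensity* is

  ```
  TNI = (Σ I_positive − mean_background · n_positive) / spheroid_area
  ```

  the right statistic for punctate or network-like stains.
- **Time-course regression.** Ordinary least squares of (fractional) depth
  on staining time, with the predicted time to complete penetration
  solving `intercept + slope·t = 1`.
- **Variance-gated group comparison.** A two-sided F-test of variance
  equality decides between the unpaired Student's t-test and Welch's
  t-test at α = 0.05, with mean ± SD summaries and star notation.
- **Protocol time accounting.** The microwave-assisted, duration-matched
  benchtop and conventional longform staining schedules ship as built-in
  step tables; totals and between-protocol time ratios are computed from
  them (fixation excluded by default).

The synthetic generator renders the four canonical stain channels —
nuclear (DAPI-like disks), nuclear envelope (lamin-like annuli), Golgi
(puncta) and cell–cell junctions (β-catenin-like boundary network) — for a
blue-noise cell packing inside the spheroid disk, attenuates each stain by
a radial front at depth `v·t`, and adds matrix background, PSF blur and
Poisson–Gaussian detector noise. Every image carries a ground-truth record
so recovery of the front by the pipeline can be tested exactly.

## Worked example

```python
from spherostain import synthgen, penetration, protocol

# a 200 µm spheroid stained for 60 min at a 0.91 µm/min front velocity
p = synthgen.mcf10a_params(field_size=512, staining_time=60.0, seed=42)
img, truth = synthgen.simulate_spheroid(p)
res = penetration.measure_penetration(
    img, "bcatenin", center_um=truth.center, radius_um=truth.radius)
print(truth.true_front_depth["bcatenin"], res.mean_depth_um, res.fractional_depth)

lib = protocol.builtin_schedules()
t_micro = protocol.total_duration(lib["microwave_mcf7_longform_comparison"])
t_long = protocol.total_duration(lib["longform_benchtop_mcf7"])
ratio = protocol.compare_schedules(
    lib["microwave_mcf7_longform_comparison"], lib["longform_benchtop_mcf7"])
```

This prints a true front depth of 54.6 µm with a measured half-max depth
of 54.5 ± 0.2 µm over 36 radial lines (fractional depth 0.545, not yet
complete), and protocol totals of 186 min = 3.1 h for the microwave
schedule vs 1300 min = 21.7 h for the longform benchtop schedule — a 7.0×
time ratio.

The same analyses are available from the shell:

```sh
spherostain simulate --preset mcf10a --times 20,60,120 --n-per-time 3 \
    --seed 1 --outdir sim/
spherostain quantify --indir sim/ --outdir results/
spherostain penetration --indir sim/ --truth sim/ground_truth.csv --outdir results/
spherostain protocol-time --name microwave_mcf7_longform_comparison \
    --name longform_benchtop_mcf7
```

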