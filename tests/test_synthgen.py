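"""Generator: geometry placement, front profile, rendering and time courses."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spherostain import synthgen
from spherostain.errors import EmptySpheroidError


class TestGeometry:
    def test_cells_contained_in_spheroid(self, noiseless_params):
        g = synthgen.generate_geometry(noiseless_params)
        d = np.hypot(*(g.cell_centers - np.asarray(g.center)).T)
        assert np.all(d <= g.radius + 1e-9)

    def test_minimum_spacing_respected(self, noiseless_params):
        g = synthgen.generate_geometry(noiseless_params)
        from scipy.spatial.distance import pdist

        assert pdist(g.cell_centers).min() >= noiseless_params.cell_min_spacing

    def test_deterministic_for_fixed_seed(self, noiseless_params):
        g1 = synthgen.generate_geometry(noiseless_params)
        g2 = synthgen.generate_geometry(noiseless_params)
        np.testing.assert_array_equal(g1.cell_centers, g2.cell_centers)

    def test_wider_spacing_places_fewer_cells(self):
        base = dict(spheroid_diameter=100.0, field_size=256, seed=3)
        dense = synthgen.generate_geometry(synthgen.SimulationParams(cell_min_spacing=8.0, **base))
        sparse = synthgen.generate_geometry(synthgen.SimulationParams(cell_min_spacing=12.0, **base))
        assert len(sparse.cell_centers) < len(dense.cell_centers)

    def test_impossible_spacing_raises(self):
        with pytest.raises(EmptySpheroidError):
            synthgen.generate_geometry(
                synthgen.SimulationParams(spheroid_diameter=20.0, cell_min_spacing=30.0, field_size=128)
            )

    def test_true_front_depth_capped_at_radius(self, small_params):
        g = synthgen.generate_geometry(small_params)  # v*t = 109.2 > R = 30
        assert all(d == g.radius for d in g.true_front_depth.values())


class TestPenetrationProfile:
    def test_surface_fully_stained(self, small_params):
        assert synthgen.penetration_profile(0.0, small_params) == 1.0

    def test_sharp_front_is_step(self, small_params):
        fd = small_params.front_depth
        assert synthgen.penetration_profile(fd - 0.01, small_params) == 1.0
        assert synthgen.penetration_profile(fd + 0.01, small_params) == 0.0

    def test_smooth_front_half_at_center(self, small_params):
        p = dataclasses.replace(small_params, front_width=5.0)
        assert synthgen.penetration_profile(p.front_depth, p) == pytest.approx(0.5)

    def test_negative_depth_rejected(self, small_params):
        with pytest.raises(ValueError):
            synthgen.penetration_profile(-1.0, small_params)

    @given(st.lists(st.floats(0, 500), min_size=2, max_size=30))
    def test_monotone_non_increasing(self, depths):
        p = synthgen.SimulationParams(front_width=8.0, staining_time=60.0, field_size=256,
                                      spheroid_diameter=100.0)
        d = np.sort(np.asarray(depths))
        prof = synthgen.penetration_profile(d, p)
        assert np.all(np.diff(prof) <= 1e-12)


class TestRender:
    def test_full_front_full_intensity(self, noiseless_image, noiseless_params):
        """Front at the radius: no radial attenuation of any structure."""
        img, g = noiseless_image
        A = noiseless_params.rim_intensity
        # nuclei carry the full amplitude wherever they are in the spheroid
        assert img.channels["dapi"].max() == A
        d = np.hypot(*(g.cell_centers - np.asarray(g.center)).T)
        deepest = g.cell_centers[np.argmin(d)]  # innermost nucleus
        r, c = int(round(deepest[1] / img.pixel_size)), int(round(deepest[0] / img.pixel_size))
        assert img.channels["dapi"][r, c] == A

    def test_structures_beyond_sharp_front_are_background(self, noiseless_params):
        p = dataclasses.replace(noiseless_params, staining_time=10.0 / 0.91)  # front at 10 µm
        img, g = synthgen.simulate_spheroid(p)
        idx = np.arange(p.field_size) * p.pixel_size
        X, Y = np.meshgrid(idx, idx)
        rgrid = np.hypot(X - g.center[0], Y - g.center[1])
        deep = rgrid < g.radius - 10.0 - p.pixel_size
        for name in synthgen.CHANNELS:
            assert img.channels[name][deep].max() == 0

    def test_no_structure_outside_spheroid(self, noiseless_image, noiseless_params):
        img, g = noiseless_image
        outside = ~g.spheroid_mask
        level = noiseless_params.rim_intensity * noiseless_params.matrix_background_fraction
        for name in synthgen.CHANNELS:
            assert img.channels[name][outside].max() == level

    def test_bit_identical_rerun(self, small_params):
        a, _ = synthgen.simulate_spheroid(small_params)
        b, _ = synthgen.simulate_spheroid(small_params)
        for name in synthgen.CHANNELS:
            np.testing.assert_array_equal(a.channels[name], b.channels[name])

    def test_staining_time_monotonicity_noise_off(self, noiseless_params):
        """Longer staining never decreases any in-spheroid pixel (noise off)."""
        times = (10.0, 30.0, 60.0)
        prev = None
        for t in times:
            p = dataclasses.replace(noiseless_params, staining_time=t, psf_sigma=0.5)
            img, g = synthgen.simulate_spheroid(p)
            stack = np.stack([img.channels[c] for c in synthgen.CHANNELS]).astype(int)
            if prev is not None:
                assert np.all(stack[:, g.spheroid_mask] >= prev[:, g.spheroid_mask])
            prev = stack

    def test_poisson_noise_variance_matches_mean(self):
        """Monte-Carlo: at poisson_scale 1, a bright pixel's sample variance ~ mean."""
        base = synthgen.SimulationParams(
            spheroid_diameter=20.0, field_size=64, cell_min_spacing=8.0,
            psf_sigma=0.0, read_noise_sd=0.0, poisson_scale=1.0, seed=0,
        )
        g = synthgen.generate_geometry(base)
        # brightest deterministic pixel: a nucleus center
        c = g.cell_centers[0]
        r, k = int(round(c[1] / base.pixel_size)), int(round(c[0] / base.pixel_size))
        vals = []
        for s in range(100):
            img = synthgen.render(g, dataclasses.replace(base, seed=s))
            vals.append(float(img.channels["dapi"][r, k]))
        vals = np.asarray(vals)
        mean, var = vals.mean(), vals.var(ddof=1)
        se = var * np.sqrt(2.0 / (len(vals) - 1))
        assert abs(var - mean) < 3 * se


class TestTimecourse:
    def test_counts_and_recorded_depths(self):
        p = synthgen.SimulationParams(
            spheroid_diameter=60.0, field_size=192, front_velocity=0.5,
            poisson_scale=0.0, read_noise_sd=0.0, psf_sigma=0.0,
        )
        images, truth = synthgen.simulate_timecourse(p, [20.0, 40.0], 2, seed=9)
        assert len(images) == 4 and len(truth) == 4
        assert truth.loc[truth.time_min == 20.0, "true_depth_bcatenin_um"].tolist() == [10.0, 10.0]
        assert truth.loc[truth.time_min == 40.0, "true_depth_bcatenin_um"].tolist() == [20.0, 20.0]

    def test_recorded_depth_is_velocity_times_time(self):
        p = synthgen.SimulationParams(spheroid_diameter=80.0, field_size=192, front_velocity=0.5)
        _, truth = synthgen.simulate_timecourse(p, [60.0], 1, seed=0)
        assert truth["true_depth_dapi_um"].iloc[0] == pytest.approx(30.0)

    def test_master_seed_determinism(self):
        p = synthgen.SimulationParams(spheroid_diameter=60.0, field_size=192)
        _, t1 = synthgen.simulate_timecourse(p, [20.0, 40.0], 2, seed=5)
        _, t2 = synthgen.simulate_timecourse(p, [20.0, 40.0], 2, seed=5)
        assert t1.equals(t2)
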