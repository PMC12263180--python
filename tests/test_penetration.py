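"""Radial profiles, rim reference, half-max crossing and penetration summary."""

import dataclasses

import numpy as np
import pytest

from spherostain import penetration, synthgen
from spherostain.errors import UnstainedPerimeterError
from tests.conftest import make_disk_image


def radial_image(field=256, px=0.5, fn=None):
    """Radially symmetric image I(r) around the field center."""
    idx = np.arange(field) * px
    X, Y = np.meshgrid(idx, idx)
    c = (field - 1) / 2.0 * px
    r = np.hypot(X - c, Y - c)
    return (fn(r) if fn else r), (c, c)


class TestExtractProfiles:
    def test_symmetric_image_gives_identical_profiles(self):
        arr, center = radial_image(fn=lambda r: 1000.0 * np.exp(-r / 30.0))
        pset = penetration.extract_profiles(arr, center, 50.0, 0.5, n_lines=8)
        spread = pset.profiles.max(axis=0) - pset.profiles.min(axis=0)
        assert spread.max() < 10.0  # interpolation tolerance on a 1000-scale image

    def test_sample_count_and_depth_grid(self):
        arr, center = radial_image()
        pset = penetration.extract_profiles(arr, center, 50.0, 0.5, n_lines=8, step_um=0.5)
        assert pset.profiles.shape == (8, int(50.0 / 0.5) + 1)
        assert pset.depths_um[0] == 0.0
        assert pset.depths_um[-1] == pytest.approx(50.0)
        assert np.all(np.diff(pset.depths_um) > 0)

    def test_ray_leaving_field_raises(self):
        arr, center = radial_image(field=64)
        with pytest.raises(ValueError):
            penetration.extract_profiles(arr, center, 100.0, 0.5)

    def test_profiles_measure_depth_from_perimeter(self):
        # I(r) = r: at depth d the intensity is radius - d
        arr, center = radial_image(fn=lambda r: r)
        pset = penetration.extract_profiles(arr, center, 40.0, 0.5, n_lines=4)
        np.testing.assert_allclose(pset.profiles[0], 40.0 - pset.depths_um, atol=0.5)


class TestRimReference:
    def test_uniform_rim(self):
        arr, center = radial_image(fn=lambda r: np.full_like(r, 100.0))
        pset = penetration.extract_profiles(arr, center, 50.0, 0.5)
        assert penetration.rim_reference(pset, 5.0) == pytest.approx(100.0)

    def test_pooled_mean_over_lines(self):
        pset = penetration.RadialProfileSet(
            depths_um=np.arange(0.0, 11.0),
            profiles=np.vstack([np.full(11, 80.0), np.full(11, 120.0)]),
            n_lines=2, sampling_step_um=1.0, radius_um=10.0,
        )
        assert penetration.rim_reference(pset, 5.0) == pytest.approx(100.0)

    def test_band_smaller_than_step_raises(self):
        pset = penetration.RadialProfileSet(
            depths_um=np.arange(0.0, 11.0), profiles=np.ones((4, 11)),
            n_lines=4, sampling_step_um=1.0, radius_um=10.0,
        )
        with pytest.raises(ValueError):
            penetration.rim_reference(pset, 0.5)


class TestHalfMaxDepth:
    def _step_profile(self):
        depths = np.arange(0.0, 51.0)
        vals = np.where(depths <= 40, 100.0, np.clip(100.0 - 25.0 * (depths - 40), 0, None))
        return depths, vals

    def test_linear_interpolation_at_crossing(self):
        depths, vals = self._step_profile()
        d, complete = penetration.half_max_depth(depths, vals, 100.0, smoothing_window=1)
        assert not complete
        assert d == pytest.approx(42.0)

    def test_uniform_profile_is_complete(self):
        depths = np.arange(0.0, 21.0)
        d, complete = penetration.half_max_depth(depths, np.full(21, 100.0), 100.0)
        assert complete and d is None

    def test_nonpositive_rim_raises(self):
        depths, vals = self._step_profile()
        with pytest.raises(UnstainedPerimeterError):
            penetration.half_max_depth(depths, vals, 0.0)

    def test_smoothing_rejects_profile_noise(self):
        depths, clean = self._step_profile()
        rng = np.random.default_rng(4)
        noisy = clean * rng.uniform(0.95, 1.05, clean.size)
        d3, _ = penetration.half_max_depth(depths, noisy, 100.0, smoothing_window=3)
        d_clean, _ = penetration.half_max_depth(depths, clean, 100.0, smoothing_window=1)
        assert abs(d3 - d_clean) <= 1.0  # within one sampling step


class TestSummarize:
    def _pset(self, profiles, radius=100.0):
        return penetration.RadialProfileSet(
            depths_um=np.arange(0.0, radius + 1.0),
            profiles=profiles, n_lines=profiles.shape[0],
            sampling_step_um=1.0, radius_um=radius,
        )

    def test_uniform_depth_and_fraction(self):
        depths = np.arange(0.0, 101.0)
        line = np.where(depths <= 40, 100.0, 0.0)
        pset = self._pset(np.vstack([line] * 4))
        res = penetration.summarize_penetration(pset, 100.0, smoothing_window=1)
        assert res.mean_depth_um == pytest.approx(40.0, abs=1.0)
        assert res.fractional_depth == pytest.approx(0.4, abs=0.01)
        assert not res.complete

    def test_all_lines_complete(self):
        pset = self._pset(np.full((4, 101), 100.0))
        res = penetration.summarize_penetration(pset, 100.0)
        assert res.complete
        assert res.mean_depth_um == pytest.approx(100.0)
        assert res.fractional_depth == 1.0
        assert res.n_lines_complete == 4

    def test_front_recovery_on_noiseless_spheroid(self):
        """Generator ground truth as oracle: sharp front at 40 µm recovered."""
        p = synthgen.SimulationParams(
            spheroid_diameter=120.0, field_size=320, staining_time=40.0 / 0.91,
            psf_sigma=0.0, poisson_scale=0.0, read_noise_sd=0.0, seed=13,
        )
        img, g = synthgen.simulate_spheroid(p)
        res = penetration.measure_penetration(
            img, "bcatenin", center_um=g.center, radius_um=g.radius
        )
        assert res.mean_depth_um == pytest.approx(
            g.true_front_depth["bcatenin"], abs=p.pixel_size
        )

    def test_staining_time_monotonicity_of_measured_depth(self):
        """Longer staining never decreases the measured mean depth (noise off)."""
        depths = []
        for t in (20.0, 50.0, 80.0):
            p = synthgen.SimulationParams(
                spheroid_diameter=120.0, field_size=320, staining_time=t,
                front_velocity=0.5, psf_sigma=0.0, poisson_scale=0.0,
                read_noise_sd=0.0, seed=13,
            )
            img, g = synthgen.simulate_spheroid(p)
            res = penetration.measure_penetration(
                img, "bcatenin", center_um=g.center, radius_um=g.radius
            )
            depths.append(res.mean_depth_um)
        assert depths == sorted(depths)

    def test_fractional_depth_bounded(self):
        img, center = make_disk_image(radius_um=50.0, field=256, value=100)
        res = penetration.measure_penetration(
            img, "dapi", center_um=center, radius_um=50.0
        )
        assert 0.0 <= res.fractional_depth <= 1.0
        assert res.complete  # uniform disk never falls below half-max
        assert res.fractional_depth == 1.0
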