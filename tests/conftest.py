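import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spherostain import synthgen

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_params():
    """A small, fast spheroid: 60 µm diameter in a 128 µm field."""
    return synthgen.SimulationParams(
        spheroid_diameter=60.0,
        field_size=256,
        staining_time=120.0,
        front_velocity=0.91,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_params(small_params):
    import dataclasses

    return dataclasses.replace(
        small_params, psf_sigma=0.0, poisson_scale=0.0, read_noise_sd=0.0
    )


@pytest.fixture(scope="session")
def noiseless_image(noiseless_params):
    geom = synthgen.generate_geometry(noiseless_params)
    return synthgen.render(geom, noiseless_params), geom


@pytest.fixture(scope="session")
def noisy_image(small_params):
    geom = synthgen.generate_geometry(small_params)
    return synthgen.render(geom, small_params), geom


def make_disk_image(radius_um=100.0, field=512, pixel_size=0.5, value=1000, background=0):
    """A perfect centered disk in the nuclear channel (geometry fixture)."""
    idx = np.arange(field) * pixel_size
    X, Y = np.meshgrid(idx, idx)
    c = (field - 1) / 2.0 * pixel_size
    disk = np.hypot(X - c, Y - c) <= radius_um
    arr = np.full((field, field), background, dtype=np.uint16)
    arr[disk] = value
    return synthgen.SpheroidImage(channels={"dapi": arr}, pixel_size=pixel_size), (c, c)
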