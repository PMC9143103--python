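import numpy as np
import pytest

from mwtrack import (
    DEFAULT_SWEEP,
    FrequencySweep,
    Scene,
    build_circular_array,
    simulate_reflection_sweep,
    to_time_domain,
)


@pytest.fixture(scope="session")
def geometry16():
    """The experimental ring: 16 antennas on a 340 mm circle, air."""
    return build_circular_array(16, 340.0, eps_r=1.0)


@pytest.fixture(scope="session")
def geometry4():
    return build_circular_array(4, 340.0, eps_r=1.0)


@pytest.fixture(scope="session")
def sweep():
    return DEFAULT_SWEEP


@pytest.fixture(scope="session")
def small_sweep():
    """A short sweep for fast IO / CLI tests."""
    return FrequencySweep(1.2e9, 5.0e9, 20)


@pytest.fixture
def point_measurement(geometry16, sweep):
    """Factory: noiseless sweep of one or more point scatterers."""

    def make(points, noise_sd=0.0, seed=None):
        scene = Scene(label="test")
        for x, y, a in points:
            scene.add_point(x, y, a)
        return simulate_reflection_sweep(
            scene, geometry16, sweep, noise_sd=noise_sd, seed=seed
        )

    return make


@pytest.fixture
def point_traces(point_measurement):
    def make(points, **kw):
        return to_time_domain(point_measurement(points, **kw))

    return make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)
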