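import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import orbitometry as om

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_phantom():
    """Default-geometry phantom pair with analytic truth (seed 1)."""
    spec = om.PhantomSpec()
    pre, post, truth = om.generate_phantom(spec, seed=1)
    return spec, pre, post, truth


@pytest.fixture(scope="session")
def quiet_phantom():
    """Noise-free phantom pair for exact-geometry assertions."""
    spec = om.PhantomSpec(boundary_noise=0.0)
    pre, post, truth = om.generate_phantom(spec, seed=1)
    return spec, pre, post, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def make_measurement(orbit_id="o1", timepoint="pre", v_orb=27000.0,
                     rectus=(1500.0, 1500.0, 1500.0, 1500.0), extra=None,
                     organ_set=om.DEFAULT_ORGAN_SET):
    """Convenience constructor for volume-arithmetic tests."""
    vols = dict(zip(om.RECTUS_ROLES, rectus))
    if extra:
        vols.update(extra)
    return om.OrbitMeasurement(orbit_id, timepoint, v_orb, vols, tuple(organ_set))
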