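import numpy as np
import pytest

from mwbreast.geometry import (EllipsoidEnvelope, LesionSpec, MediumModel,
                               PhantomSpec, build_probe_array, make_phantom)
from mwbreast.forward import frequency_grid


@pytest.fixture(scope="session")
def media():
    return MediumModel()


@pytest.fixture(scope="session")
def freqs():
    return frequency_grid(n_freq=24)


@pytest.fixture(scope="session")
def sphere50():
    """Spherical envelope of radius 50 mm at the origin."""
    return EllipsoidEnvelope((0.0, 0.0, 0.0), (50.0, 50.0, 50.0))


@pytest.fixture(scope="session")
def point_phantom():
    """Single near-point lesion, true pc_fib 35%."""
    spec = PhantomSpec(pc_fib=0.35,
                       lesions=(LesionSpec(center=(15.0, 9.0, -41.0),
                                           axes=(1.5, 1.5, 1.5),
                                           contrast=3.0),))
    return make_phantom(spec, 1)


@pytest.fixture(scope="session")
def probe_ring(point_phantom):
    return build_probe_array(100.0, point_phantom.envelope.z_grid[0], -24.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
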