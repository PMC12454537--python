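import numpy as np
import pytest

from myofield.synth import BipennateSpec, make_bipennate_mesh

E2 = np.array([0.0, 1.0, 0.0])


@pytest.fixture(scope="session")
def spec():
    """Default synthetic bipennate muscle."""
    return BipennateSpec()


@pytest.fixture(scope="session")
def mesh(spec):
    return make_bipennate_mesh(spec)


@pytest.fixture(scope="session")
def coarse_spec():
    """Coarser variant used by the mechanics tests."""
    return BipennateSpec(element_size=6.0)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_spec):
    return make_bipennate_mesh(coarse_spec)
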