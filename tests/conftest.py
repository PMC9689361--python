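import numpy as np
import pytest

from mrept.grids_io import make_grid, make_ring_masks
from mrept.phantom_forward import (
    AcquisitionSpec,
    build_phantom,
    default_phantom_spec,
    quadratic_phase,
    solve_forward_phase,
)


@pytest.fixture(scope="session")
def acq():
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def grid36():
    return make_grid(36, 36, 0.002, 0.002)


@pytest.fixture(scope="session")
def masks36(grid36):
    return make_ring_masks(grid36, 3)


@pytest.fixture(scope="session")
def phantom(acq):
    """Default brain-like phantom: (sigma truth, labels, masks)."""
    return build_phantom(default_phantom_spec())


@pytest.fixture(scope="session")
def clean_phase(phantom, acq):
    """Noise-free forward phase on the default phantom (refine=2)."""
    truth, _, _ = phantom
    return solve_forward_phase(truth, acq, refine=2)


@pytest.fixture()
def quad_phase(grid36, acq):
    """Quadratic phase whose exact reconstruction is sigma = 1 S/m."""
    return quadratic_phase(grid36, acq, sigma0=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
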