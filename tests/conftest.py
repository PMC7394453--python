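import numpy as np
import pytest

from b0synth.core_io import Volume3D
from b0synth.phantom import PhantomParams, simulate_subject


@pytest.fixture(scope="session")
def small_params() -> PhantomParams:
    """Desk-size phantom parameters shared by fast unit tests."""
    return PhantomParams(grid=(16, 16, 16), seed=7)


@pytest.fixture(scope="session")
def subject_32():
    """One 32^3 single-blip subject with a smooth (hotspot-free) field."""
    params = PhantomParams(grid=(32, 32, 32), seed=5, n_hotspots=0)
    return simulate_subject(params, pe_axis=1, readout=0.05, n_blips=1)


@pytest.fixture(scope="session")
def subject_two_blip(small_params):
    return simulate_subject(small_params, pe_axis=1, readout=0.05, n_blips=2)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_volume(data: np.ndarray, voxel: float = 2.5) -> Volume3D:
    aff = np.diag([voxel, voxel, voxel, 1.0])
    return Volume3D(np.asarray(data, dtype=np.float32), (voxel,) * 3, aff)


@pytest.fixture()
def volume_factory():
    return make_volume
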