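import numpy as np
import pytest

from blinkcomp import EmitterSet, PixelGrid, PSFModel, build_system_matrix


@pytest.fixture(scope="session")
def psf():
    return PSFModel()  # airy1d, Rayleigh radius 222 nm


@pytest.fixture(scope="session")
def ideal_grid():
    return PixelGrid.ideal(1000.0, 1.0)


@pytest.fixture(scope="session")
def camera10():
    return PixelGrid.camera(10, 100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pair_100nm(psf, ideal_grid):
    """Two emitters 100 nm apart on the ideal camera."""
    return build_system_matrix(EmitterSet.uniform(2, 100.0), ideal_grid, psf)


def random_system(rng, N=6, M=3):
    """Small random nonnegative system matrix for algebraic identities."""
    return rng.random((N, M)) + 0.05
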