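import numpy as np
import pytest

from flovis import synthetic as syn
from flovis.spectra import COMMON_GRID, Spectrum


@pytest.fixture(scope="session")
def grid():
    return COMMON_GRID


@pytest.fixture(scope="session")
def bee():
    return syn.make_viewer("bee")


@pytest.fixture(scope="session")
def uvs_bird():
    return syn.make_viewer("uvs_bird")


@pytest.fixture(scope="session")
def ctx():
    return syn.make_context()


@pytest.fixture(scope="session")
def bee_spectrum_locus(bee, ctx):
    from flovis.vision import spectrum_locus

    return spectrum_locus(bee, ctx, step=1.0)


@pytest.fixture
def red_spectrum():
    """Canonical sigmoidal red flower without a secondary peak."""
    return syn.make_flower_spectrum(syn.SpectrumParams(sp_relative_height=0.0))


@pytest.fixture
def flat_spectrum(grid):
    return Spectrum(grid, np.full(grid.size, 0.5))
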