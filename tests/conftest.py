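import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ovicolor import (
    Illuminant,
    SpectraSimConfig,
    WavelengthGrid,
    average_replicates,
    simulate_egg_spectra,
    simulate_sensitivities,
)


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def receptors():
    return simulate_sensitivities()


@pytest.fixture(scope="session")
def flat_light(grid):
    return Illuminant.flat(grid.wavelengths)


@pytest.fixture(scope="session")
def small_eggs():
    """Six clutches of three eggs, replicates already averaged."""
    cfg = SpectraSimConfig(n_clutches=6, eggs_per_clutch=3,
                           replicates_per_egg=3, rng_seed=42)
    return average_replicates(simulate_egg_spectra(cfg))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
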