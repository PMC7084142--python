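import numpy as np
import pytest

from cryoalgae import synthetic as syn
from cryoalgae.energy_budget import SpectralIrradiance


@pytest.fixture(scope="session")
def default_cross_section():
    return syn.default_cross_section()


@pytest.fixture(scope="session")
def noon_irradiance():
    """Solar-noon spectrum of the reference clear-sky day."""
    return syn.gen_irradiance_day()[12]


@pytest.fixture(scope="session")
def diel_irradiance():
    return syn.gen_irradiance_day()


@pytest.fixture
def flat_irradiance():
    """Unit photon irradiance (1 µmol·m⁻²·s⁻¹·nm⁻¹) on 280–750 nm."""
    from cryoalgae.energy_budget import energy_from_photons
    w = np.arange(280.0, 751.0)
    return SpectralIrradiance(None, w, energy_from_photons(np.ones_like(w), w))
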