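import numpy as np
import pytest

import soilbme as sb


@pytest.fixture(scope="session")
def world():
    return sb.WorldConfig()


@pytest.fixture(scope="session")
def realization(world):
    """One coupled (temperature, flux) truth draw plus the 49-point hard data."""
    temp, flux = sb.simulate_world(world, 7)
    pts = sb.sample_scheme(world.flux_grid, 49)
    hard = sb.hard_samples_from_field(flux, pts)
    return temp, flux, hard


@pytest.fixture(scope="session")
def fitted_models(realization):
    temp, flux, hard = realization
    flux_model = sb.fit_variogram_model(sb.empirical_variogram(hard, 5.0), "gaussian")
    temps = [temp.value_at(x, y) for x, y in hard.locations]
    arr = sb.fit_arrhenius(temps, hard.values)
    return flux_model, arr


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
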