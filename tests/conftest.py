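import numpy as np
import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from gmofreq.model import PlateVariabilityModel
from gmofreq.plate import PlateLayout
from gmofreq.simulate import SimulationConfig, simulate_plate


@pytest.fixture(scope="session")
def default_layout() -> PlateLayout:
    return PlateLayout.default_96well()


@pytest.fixture(scope="session")
def noisy_experiment():
    """A small, realistic two-setting synthetic plate (0.1 % GM content)."""
    return simulate_plate(SimulationConfig(seed=7, n_pseudo_settings=2))


@pytest.fixture(scope="session")
def fitted_results(noisy_experiment):
    """A moderately sized fitted analysis reused across tests."""
    model = PlateVariabilityModel(
        noisy_experiment, ks=(2, 4, 8, 16), n_combinations=400
    )
    return model.fit(seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
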