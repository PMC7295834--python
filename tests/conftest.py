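import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mrtgrid import HumanConfig, STEFAN_BOLTZMANN
from mrtgrid.synthetic import ClearSkyScene, make_flux_dataset


@pytest.fixture
def config():
    return HumanConfig()


@pytest.fixture
def enclosure_fluxes():
    """Isotropic black-body enclosure at 20 °C: the defining MRT identity."""
    L = STEFAN_BOLTZMANN * 293.15 ** 4
    return {"l_dn": L, "l_up": L, "s_diffuse": 0.0, "s_up": 0.0, "i_star": 0.0}


@pytest.fixture
def sunny_fluxes():
    """A bright mixed radiant environment (hand-checked reference case)."""
    return {"l_dn": 350.0, "l_up": 420.0, "s_diffuse": 100.0,
            "s_up": 50.0, "i_star": 800.0}


@pytest.fixture
def scene():
    return ClearSkyScene()


@pytest.fixture(scope="session")
def small_flux_ds():
    """One synthetic clear-sky day, hourly accumulation, coarse global grid."""
    scene = ClearSkyScene()
    lats = np.array([-60.0, -20.0, 0.0, 20.0, 60.0])
    lons = np.array([-150.0, -60.0, 0.0, 60.0, 150.0])
    times = pd.date_range("2018-06-01 01:00", periods=24, freq="1h")
    return make_flux_dataset(scene, lats, lons, times, 3600.0,
                             sampling_seconds=300.0)
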