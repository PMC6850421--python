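import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from beescape.experiment import baseline_scenario, default_sites, derive_seed
from beescape.landscape import build_landscape, synthesize_landscape, synthesize_weather
from beescape.pollen import ExposureConfig, default_curves


@pytest.fixture(scope="session")
def exposure_config():
    return ExposureConfig()


@pytest.fixture(scope="session")
def curves(exposure_config):
    return default_curves(exposure_config)


@pytest.fixture(scope="session")
def small_site_inputs():
    """One synthetic mid-composition landscape plus a 480-day weather series."""
    site = default_sites()[1]
    grid = synthesize_landscape(
        derive_seed(1, "landscape", site.name), site.fractions()
    )
    landscape = build_landscape(grid)
    year = synthesize_weather(derive_seed(1, "weather", site.name))
    return {
        "site": site,
        "grid": grid,
        "landscape": landscape,
        "weather": list(year) + list(year[:115]),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def scenario():
    return baseline_scenario()
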