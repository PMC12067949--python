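import numpy as np
import pytest

import larvopt as lv


@pytest.fixture(scope="session")
def params():
    return lv.ModelParams()


@pytest.fixture(scope="session")
def rates():
    return lv.synthetic_rates()


@pytest.fixture(scope="session")
def weather_std():
    """Standard synthetic weather year (seeded)."""
    return lv.generate_weather(lv.SyntheticWeatherConfig(seed=1))


@pytest.fixture(scope="session")
def sites_std():
    """Standard 70-site, three-cluster synthetic layout with doses."""
    return lv.generate_sites(lv.SyntheticSiteConfig(seed=1))


@pytest.fixture(scope="session")
def sites_small():
    """Hand-built 3-site table with known geometry and doses."""
    return lv.SiteTable(
        site_id=["a", "b", "c"],
        x=[0.0, 100.0, 0.0],
        y=[0.0, 0.0, 150.0],
        area=[1.0, 2.0, 4.0],
        vmax=[50.0, 150.0, 400.0],
        dose=[10.0, 20.0, 30.0],
    )


@pytest.fixture(scope="session")
def sim_std(sites_std, weather_std, rates, params):
    return lv.Simulator(sites_std, weather_std, rates, params)


@pytest.fixture(scope="session")
def init_std(sites_std, weather_std, params):
    rng = np.random.default_rng(0)
    return lv.default_initial_conditions(sites_std, weather_std, params, rng)
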