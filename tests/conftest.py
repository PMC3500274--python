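import numpy as np
import pytest

from phenodrivers import SimulationConfig, generate_climate_cube, generate_ndvi_cube


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=101)


@pytest.fixture(scope="session")
def small_config():
    """A 10x10 scene (2x2 climate grid), fast enough for per-test use."""
    return SimulationConfig(seed=101, fine_shape=(10, 10))


@pytest.fixture(scope="session")
def small_scene(small_config):
    cube, truth = generate_ndvi_cube(small_config)
    climate = generate_climate_cube(small_config)
    return small_config, cube, truth, climate


def make_season(
    base=0.1, amp=0.5, g1=0.07, g2=0.05, s1=135.0, s2=290.0, noise_sd=0.0, rng=None
):
    """One clean pixel-year of 24 composites on the package's composite calendar."""
    from scipy.special import expit

    from phenodrivers.calendar import COMPOSITE_START_DAYS

    t = COMPOSITE_START_DAYS.astype(float)
    series = base + amp * (expit(g1 * (t - s1)) - expit(g2 * (t - s2)))
    if noise_sd:
        series = series + (rng or np.random.default_rng(0)).normal(0, noise_sd, series.size)
    return series
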