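import numpy as np
import pytest

from rectseg.geometry import kvct_geometry, mvct_geometry
from rectseg.phantom import PhantomParams, generate_daily_scan, generate_planning_case


@pytest.fixture(scope="session")
def mv_geom():
    return mvct_geometry(10)


@pytest.fixture(scope="session")
def kv_geom():
    return kvct_geometry(28)


@pytest.fixture(scope="session")
def planning_case():
    return generate_planning_case(seed=1)


@pytest.fixture(scope="session")
def daily_scan(planning_case):
    return generate_daily_scan(planning_case, seed=2)


@pytest.fixture(scope="session")
def clean_pair():
    """Noise-free, full-contrast phantom pair: easiest study conditions."""
    params = PhantomParams(mvct_noise_sd_hu=0.0, mvct_contrast_scale=1.0,
                           gas_prob_planning=0.0)
    planning = generate_planning_case(params, seed=7)
    daily = generate_daily_scan(planning, seed=8)
    return planning, daily


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
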