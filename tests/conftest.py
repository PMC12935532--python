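import pytest

from defocarb.io_registry import ConfigBundle, GridSpec
from defocarb.synthetic import LandscapeParams, generate_landscape


@pytest.fixture(scope="session")
def default_landscape():
    """One landscape under the default study conditions."""
    return generate_landscape(LandscapeParams(seed=42))


@pytest.fixture(scope="session")
def noiseless_landscape():
    """Noiseless limit: full coverage, no label noise, no detection delay —
    every converted pixel carries its true commodity label immediately."""
    return generate_landscape(
        LandscapeParams(seed=42, noise=0.0, spatial_coverage=1.0,
                        obs_delay_max=0)
    )


@pytest.fixture(scope="session")
def small_landscape():
    return generate_landscape(
        LandscapeParams(grid=GridSpec(24, 24), seed=7)
    )


@pytest.fixture()
def config():
    return ConfigBundle()
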