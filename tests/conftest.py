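import pytest

from shearwater_census.fixtures import load_paper_fixtures
from shearwater_census.records import RunConfig
from shearwater_census.synthetic import GroundTruth


@pytest.fixture(scope="session")
def published():
    return load_paper_fixtures()


@pytest.fixture(scope="session")
def truth():
    return GroundTruth.lordhowe_like()


@pytest.fixture()
def fast_config():
    """Scaled-down MCMC settings for low-dimensional test models."""
    return RunConfig(iterations=2400, burn_in=1200, chains=3, thinning=1, seed=7)


@pytest.fixture()
def tiny_config():
    return RunConfig(iterations=1200, burn_in=600, chains=2, thinning=1, seed=7)
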