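import numpy as np
import pytest

from blcmdx import (
    AccuracyParams,
    TestPanel,
    cognitive_panel,
    load_counts_fixture,
    load_priors_fixture,
)


@pytest.fixture(scope="session")
def panel() -> TestPanel:
    return cognitive_panel()


@pytest.fixture(scope="session")
def ad_counts():
    return load_counts_fixture("ad")


@pytest.fixture(scope="session")
def mci_counts():
    return load_counts_fixture("mci")


@pytest.fixture(scope="session")
def ad_priors():
    return load_priors_fixture("ad")


@pytest.fixture(scope="session")
def mci_priors():
    return load_priors_fixture("mci")


@pytest.fixture
def rng():
    return np.random.default_rng(20230)


@pytest.fixture(scope="session")
def example_params(panel) -> AccuracyParams:
    """A realistic parameter point for the three-test panel."""
    return AccuracyParams(
        prevalence=0.2,
        se=(0.9, 0.87, 0.92),
        sp=(0.9, 0.92, 0.91),
        cov_d=(0.03,),
        cov_n=(0.02,),
    )
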