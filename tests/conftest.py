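import numpy as np
import pytest
from hypothesis import settings

from famvarkit.filters import FilterConfig
from famvarkit.simulate import (
    SimulationConfig,
    paper_family_pedigree,
    sib_pair_pedigree,
    sib_trio_pedigree,
    simulate_family_study,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def family():
    return paper_family_pedigree()


@pytest.fixture(scope="session")
def sib_pair():
    return sib_pair_pedigree()


@pytest.fixture(scope="session")
def sib_trio():
    return sib_trio_pedigree(n_affected=3, n_sibs=3)


@pytest.fixture(scope="session")
def bundle():
    return simulate_family_study(SimulationConfig(seed=1))


@pytest.fixture()
def cascade_config(bundle):
    return FilterConfig(linkage_regions=[bundle.linkage_region])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
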