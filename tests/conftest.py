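import numpy as np
import pytest

from enigo import headmodel as hm
from enigo import inverse as inv


@pytest.fixture(scope="session")
def default_space():
    return hm.build_source_grid()


@pytest.fixture(scope="session")
def default_montage():
    return hm.standard_64_montage()


@pytest.fixture(scope="session")
def default_leadfield(default_space, default_montage):
    return hm.compute_lead_field(default_space, default_montage)


@pytest.fixture(scope="session")
def laura_operator(default_leadfield, default_space):
    return inv.build_laura_operator(default_leadfield, default_space)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
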