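import pytest

from ppdcea.model import build_strategy_trees
from ppdcea.params import load_default_parameters


@pytest.fixture(scope="session")
def pset():
    return load_default_parameters()


@pytest.fixture(scope="session")
def trees(pset):
    return build_strategy_trees(pset)


@pytest.fixture()
def env(pset):
    return pset.env()
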