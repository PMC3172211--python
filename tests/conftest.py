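import pytest

from mannosite.datasets import build_main_dataset
from mannosite.synthetic import make_end_to_end_fixture


@pytest.fixture(scope="session")
def easy_chains():
    train, held = make_end_to_end_fixture("easy", seed=0)
    return train, held


@pytest.fixture(scope="session")
def easy_dataset(easy_chains):
    train, _ = easy_chains
    return build_main_dataset(train, window=17, seed=0)
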