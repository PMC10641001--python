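import numpy as np
import pytest

from noduplex import CompetitionScenario, default_weights, gen_strain_library


@pytest.fixture(scope="session")
def library():
    """Default synthetic strain library: 7 references, 4 indigenous, outgroup."""
    return gen_strain_library(seed=1, n_reference=7, n_indigenous=4, its_len=461,
                              clade_divergence=0.10)


@pytest.fixture()
def red_scenario():
    return CompetitionScenario(variety="red", weights=default_weights("red"), seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
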