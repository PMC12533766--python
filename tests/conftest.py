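import numpy as np
import pytest

from lbaspeech import (DesignSpec, IndividualParams, default_population,
                       simulate_dataset)


@pytest.fixture(scope="session")
def default_pop():
    return default_population()


@pytest.fixture(scope="session")
def tiny_spec():
    return DesignSpec(n_per_group=2, trials_per_mode=2, seed=3)


@pytest.fixture(scope="session")
def tiny_table(tiny_spec, default_pop):
    return simulate_dataset(tiny_spec, default_pop, seed=4)


@pytest.fixture()
def example_params():
    v = np.array([
        [2.0, 0.5, 0.4, 0.3],   # audio
        [2.5, 0.5, 0.4, 0.3],   # video
        [3.0, 0.5, 0.4, 0.3],   # captions
    ])
    return IndividualParams(v=v, boost_kw2=0.4, boost_kw3=0.6,
                            A=0.8, b=1.3, t0=0.3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
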