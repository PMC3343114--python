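import numpy as np
import pytest

from seqcap.dynamics import NeuronConfig
from seqcap.markov import MarkovSpec, generate_associations


@pytest.fixture(scope="session")
def small_neuron() -> NeuronConfig:
    return NeuronConfig(N=20, theta=1.0)


@pytest.fixture(scope="session")
def unbiased_spec() -> MarkovSpec:
    return MarkovSpec(f=0.5, c=0.0)


@pytest.fixture()
def small_sequence(unbiased_spec):
    return generate_associations(unbiased_spec, unbiased_spec, N=20, P=12, seed=7)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
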