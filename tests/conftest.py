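import numpy as np
import pytest

from mnb1 import (
    NeuronParams,
    SynapseParams,
    VolleySpec,
    WaveformTemplate,
    resting_state,
    run_locking,
    volley_from_fraction,
)


@pytest.fixture(scope="session")
def neuron():
    return NeuronParams()


@pytest.fixture(scope="session")
def syn():
    return SynapseParams()


@pytest.fixture(scope="session")
def template():
    return WaveformTemplate()


@pytest.fixture(scope="session")
def rest(neuron):
    return resting_state(neuron)


@pytest.fixture(scope="session")
def one_to_one_run():
    """A reference noise-free 1:1-locked run (70% sensilla, sigma 1 ms)."""
    volley = volley_from_fraction(70.0, sigma=1.0)
    train, report, sim = run_locking(
        volley=volley, visual=-35.0, return_sim=True
    )
    return volley, train, report, sim
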