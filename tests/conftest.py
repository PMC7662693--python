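import pytest

from jellyom import simulate


@pytest.fixture
def noiseless_params():
    return simulate.SimParams(seed=1, noise_cv=0.0)


@pytest.fixture
def noiseless_batch(noiseless_params):
    return simulate.simulate_batch_culture(noiseless_params)
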