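import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture(scope="session")
def tiny_feedforward():
    """A 4-input, 1-neuron network used by several kernel-level tests."""
    from plastinet.kernel import Network

    def make(seed=0, **kw):
        W = kw.pop("W_in", np.full((4, 1), 0.3))
        return Network(W.shape[0], 1, 0, W_in=W, seed=seed, **kw)

    return make
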