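import numpy as np
import pytest

from pvrnn_dyad import network as net
from pvrnn_dyad.classifier import train_default_classifier


@pytest.fixture(scope="session")
def classifier():
    """The standard ESN primitive classifier, fitted once per session."""
    return train_default_classifier(seed=0)


@pytest.fixture()
def tiny_specs():
    """A 2-layer toy network, small enough for finite-difference checks."""
    return [net.LayerSpec(3, 2, 2.0, 1.3, 1.0),
            net.LayerSpec(2, 1, 4.0, 0.7, 1.0)]


@pytest.fixture()
def tiny_params(tiny_specs):
    params = net.init_params(tiny_specs, seed=3)
    rng = np.random.default_rng(7)
    for k in params.data:  # randomize biases as well
        params.data[k] = params.data[k] + 0.1 * rng.standard_normal(
            params.data[k].shape)
    return params
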