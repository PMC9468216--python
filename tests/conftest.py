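import numpy as np
import pandas as pd
import pytest

from mmdbn.simulate import ancestral_sample, benchmark_networks, charls_like_network


@pytest.fixture(scope="session")
def benchmarks():
    return benchmark_networks()


@pytest.fixture(scope="session")
def study_network():
    return charls_like_network()


@pytest.fixture(scope="session")
def study_sample_20k(study_network):
    return ancestral_sample(study_network, 20_000, seed=20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_posterior(bn, target, evidence):
    """Independent inference oracle: condition the fully enumerated joint."""
    f = bn.enumerate_joint()
    for node, code in evidence.items():
        f = f.reduce(node, bn.state_index(node, code))
    for node in list(f.scope):
        if node != target:
            f = f.marginalize(node)
    return f.values / f.values.sum()
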