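import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import trilink as tl

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def small_dataset():
    """Planted-structure triple-layer dataset at default desk scale."""
    return tl.generate(tl.SyntheticSpec(seed=42))


@pytest.fixture
def tiny_network():
    """2 SMs x 2 miRNAs x 2 diseases with hand-enterable matrices."""
    A = np.array([[1.0, 0.0], [0.0, 1.0]])
    B = np.array([[1.0, 1.0], [0.0, 1.0]])
    S_S = np.array([[1.0, 0.3], [0.3, 1.0]])
    S_M = np.array([[1.0, 0.5], [0.5, 1.0]])
    S_D = np.array([[1.0, 0.2], [0.2, 1.0]])
    return A, B, S_S, S_M, S_D


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
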