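import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250926)


@pytest.fixture
def abc_points():
    """1-D points whose complete-linkage clustering is fully hand-checkable."""
    return np.array([[0.0], [1.0], [10.0]]), ["a", "b", "c"]
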