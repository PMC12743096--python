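import numpy as np
import pytest

from fibreguide import ModelParams


@pytest.fixture
def params():
    """Default model parameters on the small domain."""
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_psd_tensors(rng, n):
    """Random PSD 2x2 tensors with trace <= 1, as component arrays."""
    l1 = rng.uniform(0.0, 1.0, n)
    l2 = l1 * rng.uniform(0.0, 1.0, n)
    scale = np.maximum(l1 + l2, 1.0)
    l1, l2 = l1 / scale, l2 / scale
    th = rng.uniform(0.0, np.pi, n)
    c, s = np.cos(th), np.sin(th)
    oxx = l1 * c * c + l2 * s * s
    oyy = l1 * s * s + l2 * c * c
    oxy = (l1 - l2) * c * s
    return oxx, oxy, oyy
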