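import numpy as np
import pytest

from lesionseg import autograd as ag


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def float32_mode():
    """Run a test under float32 (the training precision), restoring float64."""
    ag.set_default_dtype(np.float32)
    yield
    ag.set_default_dtype(np.float64)


def set_constant_weights(module, value_fn):
    """Set every conv weight via value_fn(shape, fan_in) and zero biases."""
    from lesionseg.nn import Conv2d

    for m in module.modules():
        if isinstance(m, Conv2d):
            fan_in = m.in_channels * m.kernel_size ** 2
            m.weight.data = value_fn(m.weight.data.shape, fan_in).astype(
                m.weight.data.dtype)
            if m.bias is not None:
                m.bias.data = np.zeros_like(m.bias.data)


def randomize_weights(module, rng, scale=0.3):
    """Small random conv weights/biases (keeps tiny-block outputs well-scaled)."""
    from lesionseg.nn import Conv2d

    for m in module.modules():
        if isinstance(m, Conv2d):
            m.weight.data = rng.normal(0.0, scale, size=m.weight.data.shape)
            if m.bias is not None:
                m.bias.data = rng.normal(0.0, 0.05, size=m.bias.data.shape)
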