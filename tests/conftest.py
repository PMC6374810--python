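import numpy as np
import pytest

from msdseg.msdensenet import NetworkConfig
from msdseg.phantom import PhantomConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_network_config():
    """Smallest structurally faithful network (8+9 layers, tiny widths)."""
    return NetworkConfig(growth_rate=2, initial_channels=3,
                         decoder_compress_channels=8, decoder_up_channels=4)


@pytest.fixture
def small_phantom_config():
    """Phantom on a 32^3 grid with a tumor scaled to fit."""
    return PhantomConfig(shape=(32, 32, 32), spacing=(0.6, 0.6, 1.2),
                         semi_axes_inplane_mm=(4.0, 6.0),
                         semi_axis_axial_mm=(5.0, 8.0),
                         center_jitter_mm=1.5)


def finite_difference_grad(f, x, eps=1e-5):
    """Central finite-difference gradient of scalar f at array x."""
    g = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gf = g.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f()
        flat[i] = orig - eps
        fm = f()
        flat[i] = orig
        gf[i] = (fp - fm) / (2 * eps)
    return g
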