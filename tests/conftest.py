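import numpy as np
import pytest

from cmbseg.network import NetworkConfig, RLKUNet
from cmbseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def micro_net_cfg():
    """A minimal network configuration for fast unit tests."""
    return NetworkConfig(
        stage_channels=(4, 4, 4, 4),
        blocks_per_stage=(1, 1, 1, 1),
        rlk_kernel=5,
        cbam_reduction=2,
        droppath_rates=(0.0, 0.0, 0.0, 0.0),
    )


@pytest.fixture()
def micro_net(micro_net_cfg):
    return RLKUNet(micro_net_cfg, seed=3)


@pytest.fixture(scope="session")
def small_phantom():
    """A deterministic phantom with microbleeds and both confounder types."""
    spec = PhantomSpec(
        volume_shape=(10, 64, 64),
        cmb_diameter_range=(2.5, 4.5),
        n_cmb=3,
        n_vessels=2,
        n_calcifications=1,
        seed=42,
    )
    return generate_phantom(spec)


def numerical_gradient(f, x, eps=1e-4):
    """Central finite differences of a scalar function wrt an array."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
    return g
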