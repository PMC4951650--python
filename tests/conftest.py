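import numpy as np
import pytest

from corticrit import NetworkConfig, build_network


@pytest.fixture()
def rng(request):
    # fresh, deterministic stream per test: results never depend on which
    # other tests ran before (crc32 is stable across processes)
    import zlib

    seed = zlib.crc32(request.node.nodeid.encode())
    return np.random.default_rng([20160720, seed])


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest legal lattice (L = l = 7): one column fills the layer."""
    return NetworkConfig(L=7)


@pytest.fixture(scope="session")
def tiny_network(tiny_config):
    return build_network(tiny_config, seed=7)


@pytest.fixture(scope="session")
def small_network():
    return build_network(NetworkConfig(L=10), seed=11)


def make_manual_network(synapses, L=7):
    """Hand-built wiring for closed-form dynamics checks.

    ``synapses`` is a list of (pre_id, axon_comp, post_id, dend_comp).
    """
    from corticrit.network import Network

    cfg = NetworkConfig(L=L)
    arr = np.asarray(synapses, dtype=np.int64)
    return Network(
        config=cfg,
        pre=arr[:, 0].astype(np.int32),
        post=arr[:, 2].astype(np.int32),
        axon_comp=arr[:, 1].astype(np.uint8),
        dend_comp=arr[:, 3].astype(np.uint8),
        seed=0,
    )
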