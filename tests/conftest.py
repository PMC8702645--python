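import pytest

from qifbalance import ModelParams
from qifbalance.network import build_connectivity, simulate_network


@pytest.fixture(scope="session")
def async_params() -> ModelParams:
    """Canonical asynchronous-regime parameters (I0_e = 0.2, d_ee = 2.5, d_ii = 1)."""
    return ModelParams()


def make_pd_cut(I0_e: float, K: float = 1000.0) -> ModelParams:
    """Period-doubling cut: delta0_ee = 2.0, delta0_ii = 0.3, locked currents."""
    return ModelParams(I0_e=I0_e, I0_i=I0_e / 1.02, K=K, delta0_ee=2.0, delta0_ii=0.3)


def make_subcritical_cut(I0_e: float, K: float = 1000.0) -> ModelParams:
    """Sub-critical Hopf cut: delta0_ee = 1.58, delta0_ii = 0.3."""
    return ModelParams(I0_e=I0_e, I0_i=I0_e / 1.02, K=K, delta0_ee=1.58, delta0_ii=0.3)


@pytest.fixture(scope="session")
def pd_cut():
    return make_pd_cut


@pytest.fixture(scope="session")
def subcritical_cut():
    return make_subcritical_cut


@pytest.fixture(scope="session")
def small_net(async_params):
    """A small simulated network in the asynchronous regime (K = 64, N = 640)."""
    params = async_params.replace(K=64.0)
    conn = build_connectivity(640, 640, 64, params.delta0_ee, params.delta0_ii, seed=5)
    raster, traces = simulate_network(
        conn, params, dt=2e-3, T=5_000.0, transient=1_000.0, seed=9
    )
    return conn, params, raster, traces
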