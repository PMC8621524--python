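import numpy as np
import pytest

from epidyn import ModelParameters, ProtocolSchedule, ModelState
from epidyn import simulator


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def schedule():
    return ProtocolSchedule()


@pytest.fixture(scope="session")
def default_traces(params):
    """Full 600-s default-protocol runs for five seeds (shared across tests)."""
    traces = {}
    for seed in range(1, 6):
        traces[seed] = simulator.run(params, ProtocolSchedule(seed=seed))
    return traces


@pytest.fixture(scope="session")
def quiet_schedule():
    """No activity window, no drug block; noise still on."""
    return ProtocolSchedule(window_enabled=False, block_enabled=False)


@pytest.fixture()
def rest_state(params):
    """Noise-free fixed point of the full system (window/block disabled).

    Starts from the leak/pump balance and solves (V, K_out, Na_in)
    jointly so the residual recurrent drive and the pump-ion balance are
    included; the remaining gate drifts are < 1e-9 per ms.
    """
    from scipy.optimize import root
    from epidyn import leak_pump_rest_voltage, derivatives

    sched = ProtocolSchedule(window_enabled=False, block_enabled=False)
    v0 = leak_pump_rest_voltage(params)

    def make(x):
        v, vn, k, na = x
        return ModelState(t=0.0, V=v, V_noisy=vn, G_noise=0.0, T_syn=0.0,
                          chi_syn=1.0, chi_NMDA=1.0, G_trans=0.0, G_pers=0.0,
                          K_out=k, Na_in=na)

    def resid(x):
        dy = derivatives(make(x), sched, params)
        return [dy[0], dy[1], dy[8], dy[9]]

    sol = root(resid, [v0, v0, params.K_out_rest, params.Na_in_rest])
    assert np.max(np.abs(resid(sol.x))) < 1e-12
    return make(sol.x)
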