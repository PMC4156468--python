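import numpy as np
import pytest

from fofr import CellParameters, Protocol, basal_state, simulate_cell


@pytest.fixture(scope="session")
def params() -> CellParameters:
    return CellParameters()


@pytest.fixture(scope="session")
def basal(params) -> np.ndarray:
    return basal_state(params)


@pytest.fixture(scope="session")
def free_run_8h(params):
    """One 8-h free-running default-cell trajectory, shared across tests."""
    return simulate_cell(params, Protocol.free_running(8 * 3600.0),
                         dt_out=10.0)


@pytest.fixture(scope="session")
def vip_step_1um(params):
    """1 uM x 30 min VIP step with 1-h washout (the receptor-trafficking
    assay trajectory), shared across tests."""
    from fofr import run_vip_step
    return run_vip_step(params, 1000.0, 1800.0, 3600.0, dt_out=5.0)
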