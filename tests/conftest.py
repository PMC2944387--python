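import numpy as np
import pytest

from dbsloop import _kernels, cells


@pytest.fixture(scope="session")
def tc_params():
    return cells.load_cell_params("tc_full")


@pytest.fixture(scope="session")
def stn_params():
    return cells.load_cell_params("stn")


@pytest.fixture(scope="session")
def gpe_params():
    return cells.load_cell_params("gpe")


@pytest.fixture(scope="session")
def reduced_params():
    return cells.load_reduced_params()


@pytest.fixture(scope="session")
def tc_rest(tc_params):
    """Resting state of the full TC cell, found by relaxation."""
    pa = _kernels.tc_param_array(tc_params)
    n = int(1000 / 0.01) + 1
    z = np.zeros(n)
    out = _kernels.simulate_tc_full(np.array([-70.0, 0.8, 0.1]), pa, z, z, 0.01)
    return out[-1]


@pytest.fixture(scope="session")
def reduced_rest(reduced_params):
    """Reduced-cell state settled at the normal drive level."""
    pa = _kernels.reduced_param_array(reduced_params)
    n = int(1000 / 0.05) + 1
    out = _kernels.simulate_reduced(
        np.array([-70.0, 0.3]), pa, np.zeros(n), np.full(n, 10.0), 0.05
    )
    return out[-1]
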