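"""Shared fixtures: the two-cell model, its compiled RHS, and the handful of
reference simulations that several test modules interrogate."""

from __future__ import annotations

import numpy as np
import pytest

import tipstalk as ts
from tipstalk import fixtures

#: mildly relaxed tolerances for the many-run analyses in tests; individual
#: tests that probe solver accuracy pass their own options.
FAST_SOLVER = {"method": "BDF", "rtol": 1e-8, "atol": 1e-12}

VEGF_50 = 0.0012
VEGF_25 = 0.0006
O2_NORMOXIA = 209.0
O2_HYPOXIA = 9.95


@pytest.fixture(scope="session")
def two_cell_model():
    return ts.build_two_cell_model()


@pytest.fixture(scope="session")
def rhs(two_cell_model):
    return ts.assemble_rhs(two_cell_model)


def _sim(model, rhs, **proto_kwargs):
    proto = ts.StimulusProtocol(**proto_kwargs)
    return ts.simulate(model, proto, rhs=rhs, solver_options=dict(FAST_SOLVER))


@pytest.fixture(scope="session")
def traj_differential(two_cell_model, rhs):
    """50 vs 25 ng/mL VEGF (0.0012/0.0006 µM), normoxia, 12 h."""
    return _sim(two_cell_model, rhs, vegf_cell1=VEGF_50, vegf_cell2=VEGF_25,
                duration=12.0)


@pytest.fixture(scope="session")
def traj_equal(two_cell_model, rhs):
    return _sim(two_cell_model, rhs, vegf_cell1=VEGF_50, vegf_cell2=VEGF_50,
                duration=12.0)


@pytest.fixture(scope="session")
def traj_dapt(two_cell_model, rhs):
    """Differential VEGF with 20 µM DAPT blocking γ-secretase."""
    return _sim(two_cell_model, rhs, vegf_cell1=VEGF_50, vegf_cell2=VEGF_25,
                dapt=20.0, duration=12.0)


@pytest.fixture(scope="session")
def traj_normoxia_basal(two_cell_model, rhs):
    return _sim(two_cell_model, rhs, vegf_cell1=1e-6, vegf_cell2=1e-6,
                o2=O2_NORMOXIA, duration=12.0)


@pytest.fixture(scope="session")
def traj_hypoxia_basal(two_cell_model, rhs):
    return _sim(two_cell_model, rhs, vegf_cell1=1e-6, vegf_cell2=1e-6,
                o2=O2_HYPOXIA, duration=12.0)


@pytest.fixture()
def binding_toy():
    return fixtures.toy_network("reversible-binding")


@pytest.fixture()
def cascade_toy():
    return fixtures.toy_network("mm-cascade")


@pytest.fixture()
def mini_notch_toy():
    return fixtures.toy_network("two-cell-mini-notch")


def rel_diff(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return np.max(np.abs(a - b) / np.maximum(np.abs(a), 1e-15))
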