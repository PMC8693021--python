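import numpy as np
import pytest

from stimtwin.circuits import (CPE, Parallel, Parameter, Resistor, Series,
                               default_chamber_circuit)
from stimtwin.geometry import ChamberGeometry


@pytest.fixture
def chamber_circuit():
    """Calibrated default chamber circuit (fresh copy per test)."""
    return default_chamber_circuit()


@pytest.fixture
def fit_test_circuit():
    """R + (CPE || R_ct): the canonical interface-fit topology."""
    def make():
        return Series([
            Resistor(Parameter(150.0, min=1.0, role="medium_resistance")),
            Parallel([
                CPE(Parameter(2e-5, min=1e-9), Parameter(0.85, min=0.3, max=1.0)),
                Resistor(Parameter(5000.0, min=1.0)),
            ]),
        ])
    return make


@pytest.fixture
def nominal_geometry():
    return ChamberGeometry()


@pytest.fixture(scope="session")
def chamber_solution():
    """Coarse reference solve of the nominal chamber, shared across tests."""
    from stimtwin.fem import solve_laplace

    return solve_laplace(ChamberGeometry(), resolution=1.2)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
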