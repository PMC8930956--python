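import numpy as np
import pytest

from dmwear.cohort import Patient, default_gait_params, representative_cycle, synthesize_gait
from dmwear.implants import build_bearing_mesh, make_implant_spec
from dmwear.wear import SimulationParams


@pytest.fixture(scope="session")
def patient():
    return Patient(id="P01", sex="M", age=50.0, height=1.72, body_mass=88.8, jrf_scale=1.0)


@pytest.fixture(scope="session")
def gait_params():
    return default_gait_params()


@pytest.fixture(scope="session")
def gait(patient, gait_params):
    """One representative averaged walking cycle at the default step count."""
    return representative_cycle(patient, gait_params, n_samples=101, seed=7)


@pytest.fixture(scope="session")
def gait_coarse(patient, gait_params):
    """A shorter cycle for tests that only need the motion structure."""
    return synthesize_gait(patient, gait_params, n_samples=51, seed=7)


@pytest.fixture(scope="session")
def mesh_small():
    """Small-articulation seat of the 22.2-mm constructs at default resolution."""
    spec = make_implant_spec("DM22PE")
    return build_bearing_mesh(spec.small_seat_radius, 0.75, "small")


@pytest.fixture(scope="session")
def coarse_params():
    """Coarser mesh for pipeline-level tests where speed matters."""
    return SimulationParams(mesh_edge_mm=1.5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
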