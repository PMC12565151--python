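import numpy as np
import pytest

from corofuse.flow_profile import FlowProfileParams
from corofuse.synthetic import MotionParams, TubeParams, generate_phase_sequence


@pytest.fixture(scope="session")
def default_params() -> FlowProfileParams:
    return FlowProfileParams()


@pytest.fixture(scope="session")
def small_tube() -> TubeParams:
    return TubeParams(length=40.0, radius=2.0, n_axial=31, n_theta=12)


@pytest.fixture(scope="session")
def static_sequence(small_tube):
    """Two identical phases of a motionless tube (cheap fixture for identity checks)."""
    return generate_phase_sequence(
        small_tube, MotionParams(0.0, 0.0, 0.0), n_phases=2, seed=0
    )


@pytest.fixture(scope="session")
def moving_sequence(small_tube):
    """Standard 11-phase deforming tube."""
    return generate_phase_sequence(small_tube, MotionParams(), n_phases=11, seed=3)
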