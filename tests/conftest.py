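import numpy as np
import pytest

from jointcof.pendulum import MarkerLayout, PendulumConfig


@pytest.fixture
def config():
    """Mouse-scale default pendulum: 50 g arm, 12 deg start, 60 Hz."""
    return PendulumConfig()


@pytest.fixture
def normalized_config():
    """Round-number torques: m g L = 1 N m, W r = 0.01 N m.

    With mu = 0.05 the per-half-cycle amplitude decrement is exactly
    2 mu W r / (m g L) = 1e-3 rad in the small-angle limit.
    """
    g = 9.80665
    mass = 0.5
    com = 1.0 / (mass * g)  # m g L = 1
    return PendulumConfig(
        arm_mass=mass,
        com_distance=com,
        moment_of_inertia=0.05,
        joint_load=1.0,
        joint_radius=0.01,
    )


@pytest.fixture
def layout():
    from jointcof.pendulum import default_layout

    return default_layout()


@pytest.fixture
def symmetric_layout():
    """Arm markers at equal radius 20 mm (symmetric), far base markers."""
    arm = 20.0 * np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, 0.0], [0.0, -1.0]])
    base = 60.0 * np.array([[1.0, 1.0], [-1.0, 1.0], [-1.0, -1.0], [1.0, -1.0]]) / np.sqrt(2)
    return MarkerLayout(arm=arm, base=base)
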