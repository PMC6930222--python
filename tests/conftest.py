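import numpy as np
import pytest
from hypothesis import settings

import armfitts as af
from armfitts.arm_dynamics import default_viscosity
from armfitts.trajectory import fit_lambda, normalize_time, normalized_torque

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: reference mean arm lengths (m)
MEAN_L1, MEAN_L2 = 0.282, 0.331
START_DEG = np.array([45.0, 100.0])


@pytest.fixture(scope="session")
def mean_params():
    """Arm parameters estimated from the reference mean link lengths."""
    return af.estimate_physical_params(MEAN_L1, MEAN_L2)


@pytest.fixture(scope="session")
def start_xy(mean_params):
    return af.forward_kinematics(np.deg2rad(START_DEG), MEAN_L1, MEAN_L2)


@pytest.fixture(scope="session")
def lam():
    return fit_lambda(0.30, 0.70)


def make_reach(params, start, direction="front", D=0.5, n=101, distance=0.15):
    """Minimum-jerk reach plus its normalized-torque trajectory."""
    ang = np.deg2rad({"right": 0.0, "front": 90.0, "left": 180.0, "back": 270.0}[direction])
    target = start + distance * np.array([np.cos(ang), np.sin(ang)])
    p = params.with_viscosity(default_viscosity(direction))
    traj = af.minimum_jerk_trajectory(start, target, D, n, p)
    ntraj = normalized_torque(normalize_time(traj), p, fit_lambda(0.30, 0.70))
    return p, traj, ntraj


@pytest.fixture(scope="session")
def front_reach(mean_params, start_xy):
    """(params, trajectory, normalized trajectory) for a 0.5 s front reach."""
    return make_reach(mean_params, start_xy, "front", 0.5)


@pytest.fixture(scope="session")
def synthetic_dataset():
    """Default-scale synthetic experiment (320 successes, k_true=(0.5, 0.7)).

    Session-scoped: generated once and shared by the recovery and
    integrity tests.
    """
    subject = af.generate_subject(507)
    config = af.ExperimentConfig(seed=7, k_true=af.NoiseParams(0.5, 0.7))
    trials, truth = af.generate_dataset(config, subject)
    return trials, truth, subject, config
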