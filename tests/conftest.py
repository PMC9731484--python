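import numpy as np
import pytest

from stiffsim import (
    ArmParameters,
    ControllerParameters,
    StimulusSetConfig,
    build_stimulus_set,
    feature_table,
    simulate_steady_cycle,
)

E_FAMILY = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)


@pytest.fixture(scope="session")
def arm():
    return ArmParameters()


@pytest.fixture(scope="session")
def controller():
    return ControllerParameters()


@pytest.fixture(scope="session")
def traj_family(arm, controller):
    """Steady cycles for all six elbow-stiffness levels (simulated once)."""
    return {
        E: simulate_steady_cycle(arm, controller.with_elbow_stiffness(E))
        for E in E_FAMILY
    }


@pytest.fixture(scope="session")
def stimuli_exp1(arm, controller, traj_family):
    cfg = StimulusSetConfig(experiment=1)
    return build_stimulus_set(cfg, arm, controller, trajectories=dict(traj_family))


@pytest.fixture(scope="session")
def stimuli_exp2(arm, controller, traj_family):
    cfg = StimulusSetConfig(experiment=2)
    return build_stimulus_set(cfg, arm, controller, trajectories=dict(traj_family))


@pytest.fixture(scope="session")
def features_exp1(stimuli_exp1):
    return feature_table(stimuli_exp1)


def make_circle(radius=0.1, center=(0.0, 0.0), n=1000, closing_sample=False):
    """Uniform angular samples of a circle, optionally repeating the start."""
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=closing_sample)
    if closing_sample:
        th = np.linspace(0.0, 2 * np.pi, n + 1)
    return np.column_stack(
        [center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)]
    )


def make_ellipse(a=0.2, b=0.1, n=2000):
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([a * np.cos(th), b * np.sin(th)])
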