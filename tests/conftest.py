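import numpy as np
import pytest

from jointkal import SceneConfig, SkeletonTopology, generate_quarter_circle


@pytest.fixture
def default_scene():
    """Reference synthetic occlusion scene (seed 0, default parameters)."""
    return generate_quarter_circle(SceneConfig(seed=0))


@pytest.fixture
def two_joint_topology():
    """Elbow->wrist chain with a 0.25 m forearm."""
    return SkeletonTopology(
        joints=("elbow", "wrist"),
        parent={"elbow": "elbow", "wrist": "elbow"},
        bone_length={"wrist": 0.25},
    )


@pytest.fixture
def straight_line_trajectory():
    """Constant-velocity straight line: 10 frames, 0.05 m steps along x."""
    n = 10
    traj = np.zeros((n, 3))
    traj[:, 0] = 0.05 * np.arange(n)
    traj[:, 2] = 1.0
    return traj
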