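import numpy as np
import pytest

from gatescape.synthetic import (
    ChannelSnapshotRecord,
    GroundTruthHMM,
    simulate_feature_trajectory,
)


@pytest.fixture(scope="session")
def gt2():
    """Well-separated 2-state ground truth: closed ~0.40 nm, open ~0.65 nm."""
    return GroundTruthHMM(
        n_states=2,
        transition=np.array([[0.95, 0.05], [0.10, 0.90]]),
        emission_mean=np.array([[0.40] * 6, [0.65] * 6]),
        emission_sd=np.full((2, 6), 0.03),
        stationary=np.array([2 / 3, 1 / 3]),
        seed=0,
    )


@pytest.fixture(scope="session")
def traj2(gt2):
    return simulate_feature_trajectory(gt2, 20_000, dt=20.0, seed=11)


def make_record(frame, channel="2a", radius=1.5, residues=(10, 20, 30),
                xyz=(1.0, 2.0, 3.0), length=20.0, curvature=1.2,
                profile=None, throughput=None):
    return ChannelSnapshotRecord(
        frame_index=frame, channel=channel, bottleneck_radius=radius,
        bottleneck_residues=frozenset(residues), bottleneck_xyz=xyz,
        length=length, curvature=curvature, profile=profile,
        throughput=throughput,
    )
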