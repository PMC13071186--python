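import numpy as np
import pytest

import arenawalk as aw
from arenawalk.features import TrajectoryRecord, build_feature_table
from arenawalk.tracking import Trajectory, TrackingConfig


@pytest.fixture(scope="session")
def arena():
    return aw.default_arena()


@pytest.fixture(scope="session")
def control_truth(arena):
    """A medium-length control recording used across modules."""
    return aw.simulate_trajectory(aw.default_presets()["control"], 400, 60.0,
                                  arena, seed=11)


@pytest.fixture(scope="session")
def track_config():
    return TrackingConfig(fps=60.0, px_to_mm=0.11)


@pytest.fixture(scope="session")
def cohort_table():
    """Feature table of the full synthetic cohort (3 groups x 2 sexes x 32),
    30 s per individual at 60 fps, built once per session."""
    members = aw.make_cohort(n_per_cell=32, n_frames=1800, fps=60.0, seed=123)
    mm = members[0].truth.arena.px_to_mm
    cfg = TrackingConfig(fps=60.0, px_to_mm=mm)
    records = [
        TrajectoryRecord(
            Trajectory.from_parts(m.truth.part_positions(), 60.0, mm),
            m.truth.arena, group=m.group, sex=m.sex, uid=m.uid)
        for m in members
    ]
    return build_feature_table(records, cfg)


def truth_detections(truth, index, frame_shape=(540, 960)):
    """Ground-truth head/back part boxes as a list."""
    return list(aw.truth_detections(truth, index, frame_shape))
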