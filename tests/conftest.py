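import numpy as np
import pytest

from scpsim.datatypes import BeadTrajectory


@pytest.fixture
def ballistic_track() -> BeadTrajectory:
    """Straight-line motion at 10 nm/s along x, 1 s frames."""
    t = np.arange(30, dtype=float)
    pos = np.column_stack([10.0 * t, np.zeros_like(t)])
    return BeadTrajectory(bead_id="ballistic", times=t, positions=pos)


@pytest.fixture
def toy_track() -> BeadTrajectory:
    """The 5-frame hand-enumerable track (0,0),(1,0),(2,0),(3,0),(4,0) at 1 s."""
    t = np.arange(5, dtype=float)
    pos = np.column_stack([t, np.zeros_like(t)])
    return BeadTrajectory(bead_id="toy", times=t, positions=pos)
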