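import numpy as np
import pytest

from dendrotrace import AnalysisConfig
from dendrotrace import synthdata as sd


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def control_cohort():
    """200 granules under the control motion regime, with spines."""
    params = sd.MotionModelParams()
    spines = np.arange(8.0, 100.0, 8.0)
    tracks, truth = sd.simulate_granules(params, 200, 300.0, 100.0,
                                         spine_positions=spines, seed=42)
    return params, tracks, truth, spines


def straight_track(track_id, t, arc, y=0.0):
    """Helper: build a track directly from an arc-position series."""
    from dendrotrace.types import Track
    t = np.asarray(t, dtype=float)
    arc = np.asarray(arc, dtype=float)
    return Track(id=track_id, frames=np.arange(len(t)), t=t, x=arc,
                 y=np.full_like(arc, y), arc=arc)
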