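import numpy as np
import pytest

from olivescope import CameraModel, SimConfig
from olivescope import photometry, sim


@pytest.fixture(scope="session")
def camera() -> CameraModel:
    return CameraModel()


@pytest.fixture
def flat_trace():
    """Constant 10 s counts trace at 30 fps."""
    return photometry.FluorescenceTrace(np.full(300, 1000.0), frame_rate=30.0)


@pytest.fixture(scope="session")
def single_event_cell(camera):
    """One simulated cell with a single 10.5 ms spike (expected 300 ms rise)."""
    cfg = SimConfig(duration=20.0, spike_times=(5.0,), shoulder_widths=(10.5,),
                    f0=400.0, seed=2)
    trace, truth = sim.simulate_fluorescence(cfg, camera)
    return photometry.counts_to_power(trace, camera), truth
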