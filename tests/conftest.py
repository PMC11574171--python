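import numpy as np
import pytest

from biprkit.eyetrack import PupilTrace
from biprkit.synthetic import SimRunParams, simulate_pupil_run


@pytest.fixture(scope="session")
def standard_run():
    """A 200 s, 1 kHz run with blinks and a few closures, plus ground truth."""
    params = SimRunParams(duration_s=200.0, blink_rate_per_min=12.0,
                          closure_target_fraction=0.05, seed=42)
    return simulate_pupil_run(params)


@pytest.fixture
def make_trace():
    """Factory for hand-built traces at any stage."""

    def _make(pupil, missing=None, fs=1000.0, stage="raw", start=0.0):
        pupil = np.asarray(pupil, dtype=float)
        if missing is None:
            missing = np.zeros(pupil.size, dtype=bool)
        return PupilTrace(start_time_ms=start, sampling_hz=fs,
                          pupil=pupil, missing=np.asarray(missing, bool),
                          stage=stage)

    return _make
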