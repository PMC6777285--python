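import numpy as np
import pandas as pd
import pytest

from hrconcord import (
    DeviceErrorModel,
    HRStream,
    LabProtocol,
    Participant,
    true_hr_trajectory,
)


@pytest.fixture
def participant():
    return Participant(id="P001", age=30, resting_hr=65.0)


@pytest.fixture
def lab_protocol():
    return LabProtocol()


@pytest.fixture
def lab_truth(participant, lab_protocol):
    """Deterministic 1 Hz laboratory truth stream (20-min protocol + rest)."""
    return true_hr_trajectory(participant, lab_protocol, seed=7)


def make_stream(values, participant_id="P001", device_id="chest_strap",
                phase="lab", start="2018-04-02T09:00:00", freq="1s"):
    """Build an HRStream from raw bpm values on a regular grid."""
    idx = pd.date_range(start=start, periods=len(values), freq=freq)
    return HRStream(
        participant_id=participant_id,
        device_id=device_id,
        phase=phase,
        data=pd.Series(np.asarray(values, dtype=float), index=idx),
    )


@pytest.fixture
def zero_error_model():
    return DeviceErrorModel(sampling_period=1)
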