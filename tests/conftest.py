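import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from assemblymotifs import Session, SpikeTrain

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def build_session(spikes, duration, session_id="s1", focal="ZI"):
    """spikes: {unit_id: (area, [times])}"""
    trains = [
        SpikeTrain(uid, area, np.asarray(ts, dtype=float), session_id)
        for uid, (area, ts) in spikes.items()
    ]
    return Session(session_id, float(duration), trains, focal_area=focal)


@pytest.fixture
def make_session():
    return build_session
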