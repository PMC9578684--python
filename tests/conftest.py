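import numpy as np
import pytest

from hdmea import RecordingSession, SpikeTrain, UnitRecord


def make_unit(unit_id, times, duration=300.0, **qc):
    train = SpikeTrain(unit_id, np.asarray(times, dtype=float), 0.0, duration)
    return UnitRecord(train, **qc)


def make_session(unit_times, duration=300.0, **kwargs):
    """Build a session from {unit_id: times} (QC left unset)."""
    units = tuple(make_unit(uid, t, duration) for uid, t in unit_times.items())
    return RecordingSession(
        session_id=kwargs.pop("session_id", "s"),
        units=units,
        duration=duration,
        **kwargs,
    )


@pytest.fixture
def regular_train():
    """100 spikes at exactly 1 Hz starting at t=0.5 s."""
    return SpikeTrain("reg", 0.5 + np.arange(100.0), 0.0, 300.0)
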