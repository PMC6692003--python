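import numpy as np
import pytest

from synchroburst import ElectrodeChannel, Recording


def make_recording(spikes: dict[str, list[float]], duration_s: float = 600.0,
                   **meta) -> Recording:
    """Build a recording from an {electrode_id: spike_times} dict."""
    channels = [
        ElectrodeChannel(eid, np.asarray(times, dtype=float))
        for eid, times in spikes.items()
    ]
    return Recording(
        recording_id=meta.pop("recording_id", "test"),
        duration_s=duration_s,
        channels=channels,
        **meta,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20231201)
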