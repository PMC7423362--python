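import numpy as np
import pytest

from vigilarch.hypnogram_io import Hypnogram, LightSchedule


def make_hypnogram(labels, epoch_length=4.0, lights_on=7 * 3600.0,
                   start_at_lights_on=True, **kw):
    """Build a Hypnogram from a label string or sequence like 'WWNNR'."""
    schedule = LightSchedule(lights_on_clock_time=lights_on)
    start = lights_on if start_at_lights_on else kw.pop("start_clock_time")
    return Hypnogram(
        labels=np.array(list(labels), dtype="<U1"),
        epoch_length=epoch_length,
        start_clock_time=start,
        schedule=schedule,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
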