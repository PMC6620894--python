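import numpy as np
import pytest

from hoverbayes.interaction import AOIS, HoverEvent, HoverSequence


def make_sequence(visits, pid="p1", duration=100, gap=10):
    """Build a HoverSequence from a list of AOI codes with uniform dwell."""
    events = []
    clock = 0
    for aoi in visits:
        events.append(HoverEvent(pid, aoi, clock, clock + duration))
        clock += duration + gap
    return HoverSequence(pid, tuple(events))


@pytest.fixture
def dwell_model():
    return {a: (6.0, 0.5) for a in AOIS}


@pytest.fixture
def rng():
    return np.random.Generator(np.random.Philox(1234))
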