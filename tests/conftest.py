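import numpy as np
import pytest

from acidscale import AnchorSet, LadderMeasurement


@pytest.fixture
def triangle_measurements():
    """Overdetermined 3-node graph with a 0.1-unit inconsistency."""
    return [
        LadderMeasurement("a", "b", 1.0),
        LadderMeasurement("b", "c", 1.0),
        LadderMeasurement("a", "c", 2.1),
    ]


@pytest.fixture
def pin_a():
    return AnchorSet("fixed_single", {"a": 0.0})


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
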