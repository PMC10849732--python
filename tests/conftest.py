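import numpy as np
import pytest

from tiltpipe.schedules import impulse_schedule, tonic_schedule
from tiltpipe.scoring import FluorescenceTrace


@pytest.fixture(scope="session")
def tonic():
    return tonic_schedule()


@pytest.fixture(scope="session")
def impulse():
    return impulse_schedule()


def make_trace(frames, neuron_id="n0", roi_size=1.0, normalized=True, **kw):
    """Trace helper with sane defaults for hand-built frame series."""
    defaults = dict(
        fish_id="f0",
        genotype="sibling_pool",
        repeat_index=1,
        roi_size=roi_size,
        normalized=normalized,
    )
    defaults.update(kw)
    return FluorescenceTrace(neuron_id=neuron_id, frames=np.asarray(frames, float), **defaults)


@pytest.fixture
def flat_tonic_trace(tonic):
    return make_trace(np.full(tonic.n_frames, 100.0))
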