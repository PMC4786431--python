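import numpy as np
import pytest

from burstpause import StimulusProtocol


@pytest.fixture
def ir_protocol() -> StimulusProtocol:
    """1 s focal IR stimulus at 40 mW, the standard heat trial."""
    return StimulusProtocol("IR", onset=2.0, duration=1.0, power=40.0)


@pytest.fixture
def pulsed_protocol() -> StimulusProtocol:
    """5 cycles of 100 ms light on / 100 ms off (intermittent activation)."""
    return StimulusProtocol("light_pulsed", onset=2.0, duration=1.0, n_pulses=5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_train_times(rng, n_max=40, span=2.0):
    """Strictly increasing random spike times in [0, span)."""
    n = int(rng.integers(0, n_max))
    t = np.sort(rng.random(n) * span)
    return t[np.concatenate([[True], np.diff(t) > 1e-6])] if n else t
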