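import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from napqeeg.recording import Hypnogram
from napqeeg.staging import acquisition_filter
from napqeeg.synthetic import synthesize_signals


def one_state_hypnogram(state: str, n_epochs: int) -> Hypnogram:
    return Hypnogram(labels=np.array([state] * n_epochs))


@pytest.fixture(scope="session")
def one_state_recordings():
    """Conditioned 90-epoch single-state recordings, one per state."""
    out = {}
    for i, state in enumerate("WDNR"):
        rec = synthesize_signals(one_state_hypnogram(state, 90), seed=40 + i)
        out[state] = acquisition_filter(rec)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
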