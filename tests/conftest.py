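import numpy as np
import pytest

import cardiotrace as ct


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def short_recording():
    """One rendered synthetic beat (small frame, 2 s) shared across tests."""
    spec = ct.SyntheticRecordingSpec(frame_side=32, duration_s=2.0, seed=11)
    stack, mask, truth = ct.render_recording(spec)
    return spec, stack, mask, truth


@pytest.fixture(scope="session")
def short_trace(short_recording):
    spec, stack, mask, _ = short_recording
    return ct.compute_trace(stack, mask)
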