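import hypothesis
import numpy as np
import pytest

from cptt import make_frame_schedule

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture
def schedule():
    """The clinical 17-frame dynamic schedule (1 s delay, 10/30/60/120 s frames)."""
    return make_frame_schedule()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
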