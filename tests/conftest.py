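import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from organchip.synth import VideoTruth, generate_beating_video


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def beating_video_60():
    """A 60 BPM clip at default generator conditions (shared; read-only)."""
    truth = VideoTruth(bpm_trajectory=60.0, seed=7)
    return generate_beating_video(truth)


def make_video(**kwargs):
    """Convenience wrapper: generate a clip with overridden truth fields."""
    truth = VideoTruth(**kwargs)
    return generate_beating_video(truth)
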