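import numpy as np
import pytest

from antdet.synthetic import SynthConfig, generate_video


@pytest.fixture(scope="session")
def small_video():
    """One small synthetic clip with all noise mechanisms enabled."""
    return generate_video(SynthConfig(frame_height=64, frame_width=64,
                                      n_frames=20, n_ants=3, seed=7))


@pytest.fixture(scope="session")
def clean_video():
    """Distractor- and wind-free clip (only ants move)."""
    return generate_video(SynthConfig(frame_height=64, frame_width=64,
                                      n_frames=20, n_ants=2,
                                      n_distractors=0, wind_prob=0.0,
                                      seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
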