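import numpy as np
import pytest

from embryoflow import FrameSequence, MotionRecord, VideoSpec, synth_embryo_video


@pytest.fixture(scope="session")
def spinning_video():
    """A short disc video spinning at +0.035 rad/frame, with its truth."""
    return synth_embryo_video(VideoSpec(n_frames=40, spin_profile=0.035, seed=7))


@pytest.fixture(scope="session")
def static_video():
    """A noiseless video with no spin and no drift; motion is exactly zero."""
    return synth_embryo_video(
        VideoSpec(n_frames=30, spin_profile=0.0, background_noise_sd=0.0, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_motion_record(rng, n=64, fps=7.5):
    return MotionRecord(
        pos_angle=rng.uniform(0, 0.2, n),
        neg_angle=rng.uniform(0, 0.2, n),
        com_rho=rng.uniform(0, 5.0, n),
        com_theta=rng.uniform(-np.pi + 1e-9, np.pi, n),
        fps=fps,
        source_id="random",
    )
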