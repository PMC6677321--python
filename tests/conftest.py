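import numpy as np
import pytest

import homecage as hc


def quiet_scene(**overrides) -> hc.SceneConfig:
    """Scene with every nuisance process switched off: static background,
    no noise, no drift, no distractor jitter, no breathing."""
    defaults = dict(
        frame_size=(120, 160),
        fps=10.0,
        pixel_noise_sd=0.0,
        illumination_drift_amplitude=0.0,
        breathing_amplitude_px=0.0,
        distractor_spec=(),
        seed=0,
    )
    defaults.update(overrides)
    return hc.SceneConfig(**defaults)


@pytest.fixture
def scene_factory():
    return quiet_scene


@pytest.fixture
def wake_schedule():
    """Single WAKE bout covering five minutes."""
    return hc.make_schedule(
        300.0, {hc.State.SLEEP: 300.0, hc.State.WAKE: 1e9}, min_bout_s=300.0, seed=0
    )


@pytest.fixture
def sleep_schedule():
    return hc.StateSchedule(((0.0, 300.0, hc.State.SLEEP),), 300.0)
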