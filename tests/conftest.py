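import numpy as np
import pytest

from photopipe import (
    PhotometryRecording,
    ProtocolSpec,
    SimConfig,
    build_protocol,
    simulate_recording,
)


@pytest.fixture
def flat_recording():
    """120 Hz recording with an exact affine relation f465 = 2*f405 + 5."""
    rate = 120.0
    t = np.arange(int(10 * rate)) / rate
    f405 = 80.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
    f465 = 2.0 * f405 + 5.0
    return PhotometryRecording(time=t, f465=f465, f405=f405, rate=rate)


@pytest.fixture
def tfc_session():
    """Small noiseless 3-trial conditioning session with its ground truth."""
    schedule = build_protocol(ProtocolSpec.tfc_train(n_trials=3, iti_s=120.0), seed=11)
    config = SimConfig(duration=schedule.duration, seed=11,
                       noise_sd_465=0.0, noise_sd_405=0.0)
    rec, truth = simulate_recording(config, schedule)
    return rec, truth, schedule, config
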