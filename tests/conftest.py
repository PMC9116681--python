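from datetime import datetime

import numpy as np
import pytest

from shoalsound import CalibratedClip, HydrophoneSpec


@pytest.fixture
def pals_spec() -> HydrophoneSpec:
    """Soundscape-station chain: HTI-96-MIN-like, no gain, 1 V full scale."""
    return HydrophoneSpec(
        sensitivity=-180.0, gain=0.0, full_scale_voltage=1.0, sampling_rate=44100.0
    )


@pytest.fixture
def boat_spec() -> HydrophoneSpec:
    """Boat-recording chain: TC4013-like with amplifier and analog high-pass."""
    return HydrophoneSpec(
        sensitivity=-212.0,
        gain=32.0,
        full_scale_voltage=1.0,
        sampling_rate=44100.0,
        high_pass_cutoff=100.0,
    )


def make_tone_clip(
    freq: float,
    level_db: float,
    duration: float = 1.0,
    fs: float = 44100.0,
    site_id: str | None = None,
    start_time: datetime | None = None,
) -> CalibratedClip:
    """Sinusoid at a given rms level in dB re 1 µPa."""
    t = np.arange(int(round(duration * fs))) / fs
    amplitude = np.sqrt(2.0) * 10.0 ** (level_db / 20.0)
    return CalibratedClip(
        pressure=amplitude * np.sin(2 * np.pi * freq * t),
        sampling_rate=fs,
        site_id=site_id,
        start_time=start_time,
    )
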