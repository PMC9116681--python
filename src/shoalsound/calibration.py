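"""Hydrophone calibration: WAV sample counts to sound pressure in µPa.

An underwater recording chain maps acoustic pressure to digital counts
through the hydrophone sensitivity (dBV/µPa, typically strongly negative,
e.g. -180), any amplifier gain (dB), and the recorder's analog-to-digital
converter whose digital full scale corresponds to a known voltage.
Inverting that chain,

    pressure(t) = counts(t) / counts_fs * V_fs * 10**(-(sensitivity + gain) / 20)

yields pressure in µPa, the unit every downstream level computation
(dB re 1 µPa) is referenced to.

The counts->volts mapping uses a symmetric full scale: int16 value 32768
corresponds to ``full_scale_voltage``.  The error relative to the
asymmetric 32767 convention is below 0.001 dB.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

__all__ = [
    "HydrophoneSpec",
    "CalibratedClip",
    "load_recording",
    "center_second",
    "write_recording",
]

_INT16_FULL_SCALE = 32768.0


@dataclass(frozen=True)
class HydrophoneSpec:
    """Calibration constants for one recording chain.

    Parameters
    ----------
    sensitivity : float
        Hydrophone sensitivity in dBV/µPa (e.g. -180 for an HTI-96-MIN,
        -212 for a Reson TC4013).
    gain : float
        Amplifier gain in dB (0 if none).
    full_scale_voltage : float
        Voltage corresponding to digital full scale, in volts.
    sampling_rate : float
        Samples per second.
    high_pass_cutoff : float or None
        Cutoff of an analog high-pass filter in the chain, in Hz, if any.
        Recorded for provenance only; it is not re-applied digitally
        (the lowest analysis band edge sits far above typical cutoffs).
    """

    sensitivity: float
    gain: float
    full_scale_voltage: float
    sampling_rate: float
    high_pass_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.full_scale_voltage <= 0:
            raise ValueError(
                f"full_scale_voltage must be > 0, got {self.full_scale_voltage}"
            )

    @property
    def counts_to_micropascal(self) -> float:
        """Scale factor from a full-scale-normalised count to µPa."""
        return self.full_scale_voltage * 10.0 ** (-(self.sensitivity + self.gain) / 20.0)


@dataclass(frozen=True)
class CalibratedClip:
    """A pressure time series in µPa with its sampling metadata."""

    pressure: np.ndarray
    sampling_rate: float
    start_time: datetime | None = None
    site_id: str | None = None

    def __post_init__(self) -> None:
        pressure = np.asarray(self.pressure, dtype=np.float64)
        if not np.all(np.isfinite(pressure)):
            raise ValueError("pressure contains non-finite values")
        object.__setattr__(self, "pressure", pressure)

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return len(self.pressure) / self.sampling_rate

    @property
    def n_samples(self) -> int:
        return len(self.pressure)


def load_recording(
    path: str | Path,
    spec: HydrophoneSpec,
    *,
    start_time: datetime | None = None,
    site_id: str | None = None,
) -> CalibratedClip:
    """Read a mono 16-bit PCM WAV file and calibrate it to µPa.

    Raises
    ------
    ValueError
        If the file is multi-channel, zero-length, not 16-bit integer PCM,
        or its sampling rate disagrees with ``spec``.
    """
    path = Path(path)
    with wave.open(str(path), "rb") as wav:
        n_channels = wav.getnchannels()
        if n_channels != 1:
            raise ValueError(
                f"{path.name}: expected single-channel audio, got {n_channels} channels"
            )
        sampwidth = wav.getsampwidth()
        if sampwidth != 2:
            raise ValueError(
                f"{path.name}: expected 16-bit PCM, got {8 * sampwidth}-bit samples"
            )
        if wav.getcomptype() != "NONE":
            raise ValueError(f"{path.name}: unsupported encoding {wav.getcomptype()!r}")
        n_frames = wav.getnframes()
        if n_frames == 0:
            raise ValueError(f"{path.name}: zero-length file")
        fs = wav.getframerate()
        raw = wav.readframes(n_frames)

    counts = np.frombuffer(raw, dtype="<i2").astype(np.float64)
    if fs != spec.sampling_rate:
        raise ValueError(
            f"{path.name}: file sampling rate {fs} Hz != spec {spec.sampling_rate} Hz"
        )
    pressure = counts / _INT16_FULL_SCALE * spec.counts_to_micropascal
    return CalibratedClip(
        pressure=pressure, sampling_rate=float(fs), start_time=start_time, site_id=site_id
    )


def write_recording(path: str | Path, clip: CalibratedClip, spec: HydrophoneSpec) -> None:
    """Write a calibrated clip back to a mono 16-bit PCM WAV file.

    Inverse of :func:`load_recording`; pressures exceeding the chain's
    full-scale pressure are clipped to full scale.
    """
    counts = clip.pressure / spec.counts_to_micropascal * _INT16_FULL_SCALE
    counts = np.clip(np.round(counts), -32768, 32767).astype("<i2")
    with wave.open(str(Path(path)), "wb") as wav:
        wav.setnchannels(1)
        wav.setsampwidth(2)
        wav.setframerate(int(clip.sampling_rate))
        wav.writeframes(counts.tobytes())


def center_second(clip: CalibratedClip, window: float = 1.0) -> CalibratedClip:
    """Extract a window of ``window`` seconds centred on the clip midpoint.

    Five-minute soundscape files are summarised by a single short section
    at the halfway point of the file; a 60 s clip yields [29.5 s, 30.5 s).
    On odd sample counts the start index is floor((N - W) / 2).

    Raises
    ------
    ValueError
        If the clip is shorter than the requested window.
    """
    n_window = int(round(window * clip.sampling_rate))
    if clip.n_samples < n_window:
        raise ValueError(
            f"clip of {clip.duration:.3f} s is shorter than the {window} s window"
        )
    start = (clip.n_samples - n_window) // 2
    new_start_time = None
    if clip.start_time is not None:
        new_start_time = clip.start_time + timedelta(seconds=start / clip.sampling_rate)
    return replace(
        clip,
        pressure=clip.pressure[start : start + n_window],
        start_time=new_start_time,
    )
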