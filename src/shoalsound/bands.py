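"""Third-octave and broadband rms sound pressure levels.

Band levels are estimated from a rectangular-window FFT of the full
analysis window with power summed over the bins falling in the band.
At the standard 1 s window this gives 1 Hz resolution, so spectral
leakage is negligible for noise-like signals and the estimator is
bit-reproducible.  Band edges follow the base-10 one-third-octave
convention, center * 10**(±1/20); the difference from base-2 edges is
below 0.1 %.  Band intervals are half-open [lower, upper) so a set of
tiling bands never counts a bin twice; the DC and Nyquist bins are
excluded from every band sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibratedClip

__all__ = [
    "ThirdOctaveBand",
    "BandLevelSample",
    "STANDARD_BAND_CENTERS",
    "make_band",
    "band_level",
    "broadband_level",
    "band_level_series",
    "samples_to_frame",
    "write_band_level_csv",
    "read_band_level_csv",
]

#: Band centers (Hz) matching published manatee tone-audiogram frequencies.
STANDARD_BAND_CENTERS: tuple[float, ...] = (500.0, 1000.0, 2000.0, 4000.0, 8000.0)

_EDGE_RATIO = 10.0 ** (1.0 / 20.0)  # half a third-octave, base-10 convention


@dataclass(frozen=True)
class ThirdOctaveBand:
    """One third-octave band: center frequency and half-open edge interval."""

    center: float
    lower_edge: float
    upper_edge: float


@dataclass
class BandLevelSample:
    """One 1-s measurement: per-band TOL plus the 1-20 kHz broadband level.

    Levels are dB re 1 µPa rms.  ``tol`` maps band center (Hz) to level.
    """

    timestamp: datetime | None
    site_id: str | None
    tol: dict[float, float] = field(default_factory=dict)
    broadband_1_20k: float | None = None


def make_band(center: float) -> ThirdOctaveBand:
    """Build a third-octave band around ``center`` Hz.

    >>> band = make_band(1000.0)
    >>> round(band.lower_edge, 2), round(band.upper_edge, 2)
    (891.25, 1122.02)
    """
    if center <= 0:
        raise ValueError(f"band center must be positive, got {center}")
    return ThirdOctaveBand(
        center=center, lower_edge=center / _EDGE_RATIO, upper_edge=center * _EDGE_RATIO
    )


def _band_mean_square(
    pressure: np.ndarray, fs: float, f_lo: float, f_hi: float
) -> float:
    """Mean-square pressure (µPa²) in [f_lo, f_hi), DC and Nyquist excluded."""
    n = len(pressure)
    spectrum = np.fft.rfft(pressure)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= f_lo) & (freqs < f_hi)
    in_band[0] = False
    if n % 2 == 0:
        in_band[-1] = False
    # Parseval with one-sided doubling for the retained interior bins.
    return float(2.0 * np.sum(np.abs(spectrum[in_band]) ** 2) / n**2)


def band_level(clip: CalibratedClip, band: ThirdOctaveBand) -> float:
    """Third-octave rms sound pressure level in dB re 1 µPa.

    Raises
    ------
    ValueError
        If the band's upper edge reaches the Nyquist frequency.
    """
    nyquist = clip.sampling_rate / 2.0
    if band.upper_edge >= nyquist:
        raise ValueError(
            f"band upper edge {band.upper_edge:.1f} Hz is not below Nyquist {nyquist:.1f} Hz"
        )
    ms = _band_mean_square(clip.pressure, clip.sampling_rate, band.lower_edge, band.upper_edge)
    with np.errstate(divide="ignore"):
        return float(10.0 * np.log10(ms))


def broadband_level(
    clip: CalibratedClip, f_lo: float = 1000.0, f_hi: float = 20000.0
) -> float:
    """Rms sound pressure level over an explicit [f_lo, f_hi) band, dB re 1 µPa.

    The 1-20 kHz default matches the band used for vocal communication
    space, approximating the min-max frequency range of manatee chirps.
    """
    nyquist = clip.sampling_rate / 2.0
    if f_hi > nyquist:
        raise ValueError(f"upper edge {f_hi} Hz exceeds Nyquist {nyquist:.1f} Hz")
    if f_lo >= f_hi:
        raise ValueError(f"need f_lo < f_hi, got [{f_lo}, {f_hi})")
    ms = _band_mean_square(clip.pressure, clip.sampling_rate, f_lo, f_hi)
    with np.errstate(divide="ignore"):
        return float(10.0 * np.log10(ms))


def band_level_series(
    clip: CalibratedClip,
    bands: Sequence[ThirdOctaveBand],
    window: float = 1.0,
    hop: float = 1.0,
    *,
    include_broadband: bool = False,
) -> list[BandLevelSample]:
    """Per-window band levels over a clip, one sample per non-overlapping window.

    Timestamps (when the clip carries a start time) mark each window's start.
    Used for per-second boat-pass level series.
    """
    if hop <= 0:
        raise ValueError(f"hop must be positive, got {hop}")
    if clip.duration < window:
        raise ValueError(f"clip of {clip.duration:.3f} s shorter than window {window} s")
    n_window = int(round(window * clip.sampling_rate))
    n_hop = int(round(hop * clip.sampling_rate))
    samples: list[BandLevelSample] = []
    start = 0
    while start + n_window <= clip.n_samples:
        sub = CalibratedClip(
            pressure=clip.pressure[start : start + n_window],
            sampling_rate=clip.sampling_rate,
            site_id=clip.site_id,
        )
        ts = None
        if clip.start_time is not None:
            ts = clip.start_time + pd.Timedelta(seconds=start / clip.sampling_rate)
            ts = ts.to_pydatetime() if hasattr(ts, "to_pydatetime") else ts
        sample = BandLevelSample(
            timestamp=ts,
            site_id=clip.site_id,
            tol={band.center: band_level(sub, band) for band in bands},
            broadband_1_20k=broadband_level(sub) if include_broadband else None,
        )
        samples.append(sample)
        start += n_hop
    return samples


# ---------------------------------------------------------------------------
# CSV dialect: timestamp, site_id, TOL_<center>..., BB_1_20k

def _tol_column(center: float) -> str:
    return f"TOL_{int(center)}"


def samples_to_frame(samples: Iterable[BandLevelSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        row: dict = {"timestamp": s.timestamp, "site_id": s.site_id}
        for center, level in sorted(s.tol.items()):
            row[_tol_column(center)] = level
        row["BB_1_20k"] = s.broadband_1_20k
        rows.append(row)
    return pd.DataFrame(rows)


def write_band_level_csv(path: str | Path, frame: pd.DataFrame) -> None:
    """Write the long-format band-level table with a units header comment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# levels in dB re 1 uPa rms; timestamps ISO-8601 local time\n")
        frame.to_csv(fh, index=False)


def read_band_level_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, comment="#", parse_dates=["timestamp"])
    return frame
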