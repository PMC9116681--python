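"""Vocal communication space under practical spreading loss.

A vocalization emitted at source level SL (dB re 1 µPa at 1 m) and
propagating with practical spreading loses k*log10(r) dB by range r
metres (k = 15 by default, intermediate between cylindrical and
spherical spreading and a good fit to shallow-bay transmission-loss
measurements).  The detection distance against a broadband background
level BG is the range at which the received level meets the background:

    r = 10**((SL - BG) / k)

clamped to the 1 m reference when SL <= BG, since source levels are
referenced at 1 m and the model is undefined inside that range.  The
model has no absorption term.

The shallow-water cutoff is the lowest frequency whose wavelength fits
the water column, c / depth with c = 1500 m/s by default: a 4 m channel
accommodates frequencies above about 375 Hz, while 1.5 m of water
strips components at 1 kHz and below.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "SpreadingModel",
    "received_level",
    "detection_distance",
    "distance_ratio",
    "cutoff_frequency",
    "detection_distance_table",
    "STUDY_SOURCE_LEVELS",
]

import math

#: Chirp source levels (dB re 1 µPa @ 1 m): mean - sd, mean, mean + sd.
STUDY_SOURCE_LEVELS: tuple[float, ...] = (115.5, 122.0, 128.5)

DEFAULT_SOUND_SPEED = 1500.0  # m/s, nominal shallow seawater


@dataclass(frozen=True)
class SpreadingModel:
    """Transmission loss k*log10(r / reference_distance)."""

    k: float = 15.0
    reference_distance: float = 1.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"spreading coefficient k must be positive, got {self.k}")
        if self.reference_distance <= 0:
            raise ValueError("reference distance must be positive")

    def loss(self, r: float) -> float:
        return self.k * math.log10(r / self.reference_distance)


def received_level(sl: float, r: float, model: SpreadingModel = SpreadingModel()) -> float:
    """Level (dB) of a source of level ``sl`` @ 1 m received at range ``r`` m."""
    if r < model.reference_distance:
        raise ValueError(
            f"range {r} m is inside the {model.reference_distance} m reference"
        )
    return sl - model.loss(r)


def detection_distance(
    sl: float, bg: float, model: SpreadingModel = SpreadingModel()
) -> float:
    """Range (m) at which the received level falls to the background level.

    Clamped to the reference distance when ``sl <= bg``.

    >>> detection_distance(122.0, 107.0)   # 15 dB excess, k = 15
    10.0
    """
    if not (math.isfinite(sl) and math.isfinite(bg)):
        raise ValueError("source and background levels must be finite")
    if sl <= bg:
        return model.reference_distance
    return model.reference_distance * 10.0 ** ((sl - bg) / model.k)


def distance_ratio(delta_sl: float, model: SpreadingModel = SpreadingModel()) -> float:
    """Factor by which detection distance grows per ``delta_sl`` dB of source level."""
    return 10.0 ** (delta_sl / model.k)


def cutoff_frequency(depth: float, sound_speed: float = DEFAULT_SOUND_SPEED) -> float:
    """Lowest frequency (Hz) whose wavelength fits a water column of ``depth`` m.

    >>> cutoff_frequency(4.0)
    375.0
    """
    if depth <= 0:
        raise ValueError(f"depth must be positive, got {depth}")
    return sound_speed / depth


def detection_distance_table(
    site_backgrounds: Mapping[str, float],
    source_levels: Sequence[float] = STUDY_SOURCE_LEVELS,
    model: SpreadingModel = SpreadingModel(),
    *,
    round_decimals: int = 1,
) -> pd.DataFrame:
    """Detection distance (m) per site x source level.

    ``site_backgrounds`` maps site id to its median broadband background
    level (dB re 1 µPa rms, 1-20 kHz).  Distances are rounded to one
    decimal metre by default.
    """
    table = pd.DataFrame(
        {
            site: [
                round(detection_distance(sl, bg, model), round_decimals)
                for sl in source_levels
            ]
            for site, bg in site_backgrounds.items()
        },
        index=pd.Index(list(source_levels), name="source_level_db"),
    )
    return table


def write_commspace_csv(path: str | Path, table: pd.DataFrame) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# detection distance in m; source levels in dB re 1 uPa @ 1 m\n")
        table.to_csv(fh)
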