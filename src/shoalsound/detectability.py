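"""When does an approaching boat become audible?

A boat pass is a per-second series of third-octave levels (TOL_BOAT)
aligned to the closest point of approach (CPA, t = 0; negative t is
before).  Within each band the boat is taken to become detectable at
the earliest (most negative) second at which TOL_BOAT strictly exceeds
both the background level in that band (TOL_BG, e.g. the stratum median
or 95th percentile) and the tone-audiogram detection threshold measured
under quiet laboratory conditions.  Third-octave bands stand in for the
auditory filter, so the tone threshold can be compared to a band level.

The search runs over t in [-30, 0]; post-CPA seconds are carried for
plotting only.  A pass already above the gate at t = -30 is reported as
censored (">= 30 s" of warning); one never above it by t = 0 is
not-detectable.  Warning time converts to distance via the boat speed
(statute mph x 0.44704 m/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "MPH_TO_MS",
    "Audiogram",
    "BoatPass",
    "DetectionResult",
    "earliest_detection",
    "limiting_factor",
    "reaction_distance",
    "detection_grid",
]

MPH_TO_MS = 0.44704  # exact statute conversion

THRESHOLD_LIMITED = "threshold_limited"
NOISE_LIMITED = "noise_limited"
CENSORED = "censored"  # gate already exceeded at the window edge
DETECTED = "detected"
NOT_DETECTABLE = "not_detectable"


@dataclass(frozen=True)
class Audiogram:
    """Tone detection thresholds: band center (Hz) -> dB re 1 µPa."""

    thresholds: Mapping[float, float]

    def threshold(self, band_center: float) -> float:
        try:
            return self.thresholds[band_center]
        except KeyError:
            raise KeyError(
                f"audiogram has no threshold for the {band_center} Hz band"
            ) from None

    def __post_init__(self) -> None:
        for center, level in self.thresholds.items():
            if not math.isfinite(level):
                raise ValueError(f"non-finite threshold for {center} Hz band")


@dataclass
class BoatPass:
    """CPA-aligned per-second band levels for one pass at one speed.

    ``levels`` is indexed by integer time relative to CPA in seconds
    (negative before CPA) with one column per band center (Hz).
    The analysis window is [-30, +3] s.
    """

    speed_mph: float
    levels: pd.DataFrame
    receiver_depth_label: str = "1 m"
    site_id: str | None = None

    def __post_init__(self) -> None:
        times = self.levels.index.to_numpy()
        if len(times) > 1 and not (pd.Series(times).diff().dropna() == 1).all():
            raise ValueError("boat-pass times must be consecutive whole seconds")
        if times.min() < -30 or times.max() > 3:
            raise ValueError("boat-pass times must lie within [-30, +3] s of CPA")

    @property
    def speed_ms(self) -> float:
        return self.speed_mph * MPH_TO_MS


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of the detection gate for one band of one pass."""

    band_center: float
    status: str  # detected | censored | not_detectable
    seconds_before_cpa: float | None  # warning time; None unless detected
    limiting_factor: str  # threshold_limited | noise_limited
    distance_at_detection: float | None  # m; None unless detected


def limiting_factor(audiogram: Audiogram, bg_level: float, band_center: float) -> str:
    """Which term of the gate binds: the audiogram or the background.

    Threshold-limited iff threshold > background; a tie counts as
    noise-limited (the background alone already enforces the gate).
    """
    return THRESHOLD_LIMITED if audiogram.threshold(band_center) > bg_level else NOISE_LIMITED


def earliest_detection(
    boat_pass: BoatPass, audiogram: Audiogram, bg_levels: Mapping[float, float]
) -> dict[float, DetectionResult]:
    """Earliest pre-CPA second at which each band's boat level exceeds the gate.

    The gate is max(audiogram threshold, background level); "exceeds" is
    strict.  The earliest crossing is reported even if the level later
    dips back below the gate.

    Returns a dict keyed by band center.

    Raises
    ------
    KeyError
        If a band in the pass is missing from the audiogram or background.
    """
    results: dict[float, DetectionResult] = {}
    pre_cpa = boat_pass.levels.loc[boat_pass.levels.index <= 0]
    for band_center in boat_pass.levels.columns:
        if band_center not in bg_levels:
            raise KeyError(f"no background level for the {band_center} Hz band")
        gate = max(audiogram.threshold(band_center), bg_levels[band_center])
        factor = limiting_factor(audiogram, bg_levels[band_center], band_center)
        exceeded = pre_cpa.index[pre_cpa[band_center] > gate]
        if len(exceeded) == 0:
            results[band_center] = DetectionResult(
                band_center, NOT_DETECTABLE, None, factor, None
            )
            continue
        t_first = int(exceeded.min())
        if t_first == pre_cpa.index.min() and t_first == -30:
            # already above the gate when the window opens: warning >= 30 s
            results[band_center] = DetectionResult(band_center, CENSORED, None, factor, None)
            continue
        warning = float(-t_first)
        results[band_center] = DetectionResult(
            band_center,
            DETECTED,
            warning,
            factor,
            reaction_distance(warning, boat_pass.speed_mph),
        )
    return results


def reaction_distance(seconds_before_cpa: float, speed_mph: float) -> float:
    """Distance (m, nearest metre) of the boat at a given warning time.

    >>> reaction_distance(15, 7)
    47.0
    >>> reaction_distance(15, 26.2)
    176.0
    """
    if seconds_before_cpa < 0:
        raise ValueError("warning time must be non-negative")
    if speed_mph <= 0:
        raise ValueError("speed must be positive")
    return float(round(speed_mph * MPH_TO_MS * seconds_before_cpa))


def detection_grid(
    passes: list[BoatPass],
    audiogram: Audiogram,
    bg_table: pd.DataFrame,
) -> pd.DataFrame:
    """Detection outcomes over site x speed x background percentile x band.

    ``bg_table`` is a long-form summary with columns site_id, percentile
    and one ``TOL_<center>`` column per band (the soundscape summary
    dialect).  Returns one row per combination with warning time,
    censoring status, limiting factor and distance.
    """
    rows = []
    for boat_pass in passes:
        for _, bg_row in bg_table.iterrows():
            bg_levels = {
                float(col.split("_")[1]): bg_row[col]
                for col in bg_table.columns
                if col.startswith("TOL_")
            }
            bg_levels = {c: v for c, v in bg_levels.items() if c in boat_pass.levels.columns}
            results = earliest_detection(boat_pass, audiogram, bg_levels)
            for band_center, res in results.items():
                rows.append(
                    {
                        "site_id": bg_row["site_id"],
                        "speed_mph": boat_pass.speed_mph,
                        "depth_label": boat_pass.receiver_depth_label,
                        "bg_percentile": bg_row["percentile"],
                        "band_center_hz": band_center,
                        "status": res.status,
                        "seconds_before_cpa": res.seconds_before_cpa,
                        "limiting_factor": res.limiting_factor,
                        "distance_m": res.distance_at_detection,
                    }
                )
    return pd.DataFrame(rows)


def write_detection_csv(path: str | Path, grid: pd.DataFrame) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "# warning time in s before CPA (censored = gate already exceeded 30 s out);"
            " distance in m\n"
        )
        grid.to_csv(fh, index=False)
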