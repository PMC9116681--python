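"""Stratified soundscape statistics.

Band-level samples are stratified by site, season (membership in a
configured winter or summer campaign window) and diel period
(day 07:00-18:59, night 19:00-06:59, local clock time), and summarised
by percentiles of the dB values.  Percentiles use linear interpolation
between order statistics and are computed in the dB domain, matching
how third-octave level distributions are conventionally presented;
median (p50) describes typical conditions and p95 elevated ones.
Timestamps are naive local clock time; no timezone arithmetic is done.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CampaignPeriod",
    "StratumKey",
    "SoundscapeSummary",
    "classify_diel",
    "classify_season",
    "add_strata",
    "summarize",
    "summarize_all",
    "tally",
    "write_summary_csv",
]

POOLED = "pooled"
_DAY_START_HOUR = 7
_NIGHT_START_HOUR = 19


@dataclass(frozen=True)
class CampaignPeriod:
    """One contiguous recording campaign window with its season label."""

    season: str  # "winter" or "summer"
    start: datetime
    end: datetime  # exclusive

    def __post_init__(self) -> None:
        if self.season not in ("winter", "summer"):
            raise ValueError(f"season must be winter or summer, got {self.season!r}")
        if self.end <= self.start:
            raise ValueError("campaign end must be after start")

    def contains(self, timestamp: datetime) -> bool:
        return self.start <= timestamp < self.end


@dataclass(frozen=True)
class StratumKey:
    """A (site, season, diel) cell; any axis may be pooled."""

    site_id: str = POOLED
    season: str = POOLED
    diel: str = POOLED

    def __post_init__(self) -> None:
        if self.season not in ("winter", "summer", POOLED):
            raise ValueError(f"invalid season {self.season!r}")
        if self.diel not in ("day", "night", POOLED):
            raise ValueError(f"invalid diel period {self.diel!r}")


@dataclass
class SoundscapeSummary:
    """Percentile levels per band (and broadband) for one stratum."""

    stratum: StratumKey
    n: int
    levels: pd.DataFrame  # index: percentile (float); columns: level columns


def classify_diel(timestamp: datetime) -> str:
    """Day iff local clock time falls in [07:00, 19:00); otherwise night."""
    return "day" if _DAY_START_HOUR <= timestamp.hour < _NIGHT_START_HOUR else "night"


def classify_season(timestamp: datetime, campaigns: Sequence[CampaignPeriod]) -> str:
    """Season label of the campaign period containing ``timestamp``.

    Raises
    ------
    ValueError
        If the timestamp falls outside every configured campaign window.
    """
    for period in campaigns:
        if period.contains(timestamp):
            return period.season
    raise ValueError(f"timestamp {timestamp.isoformat()} outside all campaign periods")


def add_strata(
    frame: pd.DataFrame, campaigns: Sequence[CampaignPeriod] | None = None
) -> pd.DataFrame:
    """Annotate a band-level table with ``diel`` and (if configured) ``season``."""
    out = frame.copy()
    timestamps = pd.to_datetime(out["timestamp"])
    out["diel"] = np.where(
        (timestamps.dt.hour >= _DAY_START_HOUR) & (timestamps.dt.hour < _NIGHT_START_HOUR),
        "day",
        "night",
    )
    if campaigns is not None:
        out["season"] = [classify_season(ts, campaigns) for ts in timestamps]
    return out


def _stratum_mask(frame: pd.DataFrame, stratum: StratumKey) -> pd.Series:
    mask = pd.Series(True, index=frame.index)
    if stratum.site_id != POOLED:
        mask &= frame["site_id"] == stratum.site_id
    if stratum.season != POOLED:
        mask &= frame["season"] == stratum.season
    if stratum.diel != POOLED:
        mask &= frame["diel"] == stratum.diel
    return mask


def _level_columns(frame: pd.DataFrame) -> list[str]:
    return [c for c in frame.columns if c.startswith("TOL_") or c.startswith("BB_")]


def summarize(
    frame: pd.DataFrame,
    stratum: StratumKey,
    percentiles: Sequence[float] = (50.0, 95.0),
) -> SoundscapeSummary:
    """Percentile levels for one stratum, computed on dB values.

    Raises
    ------
    ValueError
        If no samples fall in the stratum (the error names it).
    """
    sub = frame[_stratum_mask(frame, stratum)]
    if len(sub) == 0:
        raise ValueError(f"no samples in stratum {stratum}")
    cols = _level_columns(frame)
    table = pd.DataFrame(
        {
            col: np.percentile(sub[col].dropna().to_numpy(), percentiles)
            for col in cols
            if sub[col].notna().any()
        },
        index=pd.Index(list(percentiles), name="percentile"),
    )
    return SoundscapeSummary(stratum=stratum, n=len(sub), levels=table)


def summarize_all(
    frame: pd.DataFrame,
    strata: Iterable[StratumKey],
    percentiles: Sequence[float] = (50.0, 95.0),
) -> pd.DataFrame:
    """Long-form summary table: one row per stratum x percentile."""
    rows = []
    for stratum in strata:
        summary = summarize(frame, stratum, percentiles)
        for pct, row in summary.levels.iterrows():
            record = {
                "site_id": stratum.site_id,
                "season": stratum.season,
                "diel": stratum.diel,
                "percentile": pct,
                "n": summary.n,
            }
            record.update(row.to_dict())
            rows.append(record)
    return pd.DataFrame(rows)


def tally(frame: pd.DataFrame, by: Sequence[str] = ("site_id",)) -> pd.DataFrame:
    """Sample counts per stratum; marginal sums equal the total by construction."""
    if len(frame) == 0:
        return pd.DataFrame(columns=[*by, "n"])
    counts = frame.groupby(list(by), observed=True).size().reset_index(name="n")
    return counts


def write_summary_csv(path: str | Path, summary: pd.DataFrame) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# percentile levels in dB re 1 uPa rms\n")
        summary.to_csv(fh, index=False)
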