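"""Synthetic soundscapes with known ground truth.

Every stage of the pipeline can be exercised without field recordings:

* :func:`synth_background` renders a calibrated clip as a sum of
  independent band-limited Gaussian noise components, each scaled so its
  in-band rms hits a target third-octave level exactly in expectation.
* :func:`synth_boat_pass` generates a CPA-aligned per-second level table
  from pass geometry: range r(t) = sqrt((v t)^2 + d_cpa^2) and received
  level = source level - k*log10(r), mirroring a constant-speed pass
  within a metre or two of the receiver.
* :func:`synth_campaign` emulates a monitoring deployment: one 1-s
  sample per 5-minute slot per site over two contiguous 14-day campaign
  windows (winter and summer), with site/season/diel level structure,
  Gaussian jitter in the dB domain, and i.i.d. per-slot dropout
  (the field deployments stored about 94 % of slots).

All generators are deterministic under a fixed seed, and each returns a
truth record echoing its configuration so tests can verify recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bands import make_band
from .calibration import CalibratedClip
from .stats import CampaignPeriod

__all__ = [
    "StratumTargets",
    "SceneConfig",
    "BoatPassConfig",
    "synth_background",
    "synth_boat_pass",
    "synth_campaign",
    "default_scene",
]

_SLOT_SECONDS = 300  # 5-minute storage cadence


@dataclass(frozen=True)
class StratumTargets:
    """Target levels for one (season, diel) cell of one site, dB re 1 µPa."""

    tol: Mapping[float, float]  # band center -> TOL
    broadband_1_20k: float


@dataclass
class SceneConfig:
    """A multi-site campaign scenario.

    ``sites`` maps site id -> (season, diel) -> targets.  ``jitter_sd``
    is the per-sample Gaussian spread applied in the dB domain around
    the stratum target (real shallow-water levels fluctuate by a few dB
    between 5-minute samples).  ``dropout`` is the i.i.d. probability a
    slot fails to record.
    """

    sites: Mapping[str, Mapping[tuple[str, str], StratumTargets]]
    campaigns: Sequence[CampaignPeriod]
    dropout: float = 0.06
    jitter_sd: float = 3.0
    cadence_s: int = _SLOT_SECONDS
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")
        periods = sorted(self.campaigns, key=lambda p: p.start)
        for a, b in zip(periods, periods[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"campaign periods overlap: {a.season} ends {a.end}, "
                    f"{b.season} starts {b.start}"
                )


@dataclass
class BoatPassConfig:
    """Geometry and source spectrum for one synthetic boat pass.

    The study boat ran at 7, 17.4 and 26.2 mph and passed within 1-2 m
    of the receiver; ``source_tol`` gives the per-band level at the 1 m
    reference and ``k`` the spreading coefficient.
    """

    speed_mph: float
    source_tol: Mapping[float, float]  # band center -> dB @ 1 m
    cpa_offset_m: float = 1.5
    k: float = 15.0
    t_start: int = -30
    t_end: int = 3
    level_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_mph <= 0:
            raise ValueError("speed must be positive")
        if self.cpa_offset_m <= 0:
            raise ValueError("CPA offset must be positive")


def synth_background(
    targets: Mapping[float, float],
    duration: float = 1.0,
    fs: float = 44100.0,
    seed: int = 0,
) -> tuple[CalibratedClip, dict]:
    """Band-limited Gaussian noise clip hitting target third-octave levels.

    Each band's component is white Gaussian noise FFT-filtered to the
    band and rescaled so its realized in-band rms equals the target
    exactly; components are independent across bands.

    Returns the clip and a truth record (targets, seed, fs).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    nyquist = fs / 2.0
    pressure = np.zeros(n)
    for center, level_db in targets.items():
        band = make_band(center)
        if band.upper_edge >= nyquist:
            raise ValueError(
                f"band {center} Hz (upper edge {band.upper_edge:.0f} Hz) infeasible "
                f"at fs {fs} Hz"
            )
        white = rng.standard_normal(n)
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n, d=1.0 / fs)
        keep = (freqs >= band.lower_edge) & (freqs < band.upper_edge)
        keep[0] = False
        if n % 2 == 0:
            keep[-1] = False
        spectrum[~keep] = 0.0
        component = np.fft.irfft(spectrum, n=n)
        rms = np.sqrt(np.mean(component**2))
        target_rms = 10.0 ** (level_db / 20.0)
        pressure += component * (target_rms / rms)
    clip = CalibratedClip(pressure=pressure, sampling_rate=fs)
    truth = {"targets": dict(targets), "seed": seed, "fs": fs, "duration": duration}
    return clip, truth


def synth_boat_pass(cfg: BoatPassConfig) -> tuple[pd.DataFrame, dict]:
    """Per-second CPA-aligned received-level table for a straight-line pass.

    Received level in each band is source TOL minus k*log10(r(t)) with
    r(t) = sqrt((v t)^2 + cpa_offset^2), optionally plus seeded Gaussian
    jitter.  Index is whole seconds relative to CPA over
    [t_start, t_end]; columns are band centers.
    """
    from .detectability import MPH_TO_MS

    rng = np.random.default_rng(cfg.seed)
    times = np.arange(cfg.t_start, cfg.t_end + 1)
    v = cfg.speed_mph * MPH_TO_MS
    r = np.sqrt((v * times) ** 2 + cfg.cpa_offset_m**2)
    data = {}
    for center, sl in cfg.source_tol.items():
        levels = sl - cfg.k * np.log10(r)
        if cfg.level_jitter_sd > 0:
            levels = levels + rng.normal(0.0, cfg.level_jitter_sd, size=len(times))
        data[center] = levels
    table = pd.DataFrame(data, index=pd.Index(times, name="time_rel_cpa_s"))
    truth = {
        "speed_mph": cfg.speed_mph,
        "speed_ms": v,
        "cpa_offset_m": cfg.cpa_offset_m,
        "k": cfg.k,
        "source_tol": dict(cfg.source_tol),
        "range_m": r,
        "seed": cfg.seed,
    }
    return table, truth


def synth_campaign(cfg: SceneConfig) -> tuple[pd.DataFrame, dict]:
    """Band-level sample table for a full multi-site campaign.

    One row per surviving 5-minute slot per site per campaign period,
    in the band-level CSV dialect (timestamp, site_id, TOL_<center>...,
    BB_1_20k) plus ``season`` and ``diel`` annotation columns.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for site_id, strata in cfg.sites.items():
        for period in cfg.campaigns:
            n_slots = int((period.end - period.start).total_seconds() // cfg.cadence_s)
            kept = rng.random(n_slots) >= cfg.dropout
            jitter_shape = None
            for slot in range(n_slots):
                if not kept[slot]:
                    continue
                ts = period.start + timedelta(seconds=slot * cfg.cadence_s)
                diel = "day" if 7 <= ts.hour < 19 else "night"
                targets = strata[(period.season, diel)]
                if jitter_shape is None:
                    jitter_shape = len(targets.tol) + 1
                jitter = rng.normal(0.0, cfg.jitter_sd, size=jitter_shape)
                row: dict = {"timestamp": ts, "site_id": site_id, "season": period.season, "diel": diel}
                for j, (center, level) in enumerate(sorted(targets.tol.items())):
                    row[f"TOL_{int(center)}"] = level + jitter[j]
                row["BB_1_20k"] = targets.broadband_1_20k + jitter[-1]
                rows.append(row)
    frame = pd.DataFrame(rows)
    truth = {
        "sites": cfg.sites,
        "campaigns": list(cfg.campaigns),
        "dropout": cfg.dropout,
        "jitter_sd": cfg.jitter_sd,
        "seed": cfg.seed,
        "slots_per_period": int(
            (cfg.campaigns[0].end - cfg.campaigns[0].start).total_seconds() // cfg.cadence_s
        ),
    }
    return frame, truth


def default_scene(
    seed: int = 0, dropout: float = 0.06, jitter_sd: float = 3.0
) -> SceneConfig:
    """The study conditions: four sites, two 14-day campaigns, 5-min cadence.

    Level structure follows the qualitative field pattern: Tidy quietest,
    then Bayou Hammock, then Hillview and PCM; Hillview louder than PCM
    at 0.5-1 kHz but quieter at 2-8 kHz; every band a few dB higher in
    summer than winter and in day than night.  Broadband (1-20 kHz)
    medians are anchored so the communication-space model reproduces the
    field-scale detection distances (about 110 m at Tidy down to 9 m at
    PCM for a loud chirp).
    """
    bands = (500.0, 1000.0, 2000.0, 4000.0, 8000.0)
    # per-site base TOLs (winter, night) and broadband anchors
    base = {
        "Tidy": ({500.0: 88, 1000.0: 86, 2000.0: 85, 4000.0: 84, 8000.0: 82}, 97.9),
        "BayouHammock": ({500.0: 96, 1000.0: 94, 2000.0: 93, 4000.0: 92, 8000.0: 90}, 110.7),
        "Hillview": ({500.0: 103, 1000.0: 100, 2000.0: 96, 4000.0: 95, 8000.0: 93}, 111.8),
        "PCM": ({500.0: 101, 1000.0: 98, 2000.0: 99, 4000.0: 98, 8000.0: 96}, 114.2),
    }
    season_boost = {"winter": 0.0, "summer": 2.0}
    diel_boost = {"night": 0.0, "day": 2.0}
    sites: dict[str, dict[tuple[str, str], StratumTargets]] = {}
    for site_id, (tols, bb) in base.items():
        cells = {}
        for season in ("winter", "summer"):
            for diel in ("day", "night"):
                boost = season_boost[season] + diel_boost[diel]
                cells[(season, diel)] = StratumTargets(
                    tol={c: tols[c] + boost for c in bands},
                    broadband_1_20k=bb + boost,
                )
        sites[site_id] = cells
    campaigns = [
        CampaignPeriod("winter", datetime(2019, 1, 15), datetime(2019, 1, 29)),
        CampaignPeriod("summer", datetime(2019, 8, 1), datetime(2019, 8, 15)),
    ]
    return SceneConfig(
        sites=sites, campaigns=campaigns, dropout=dropout, jitter_sd=jitter_sd, seed=seed
    )
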