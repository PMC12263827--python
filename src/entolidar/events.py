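"""Observation selection and ecological labeling of transit events.

The analysis keeps only transits long enough to resolve the lowest wingbeat
frequencies: signal duration strictly above 25 ms and at least 80 time
samples per channel. Each accepted event is then placed in a vertical layer
from straight-line beam geometry — shrub below 2.5 m, canopy 2.5–25 m, open
sky above 25 m — and in a diel time class (dawn / diurnal / dusk /
nocturnal) from its local clock time; dawn and dusk together form the
crepuscular class used by the temporal ternary diagram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import TransitSignal

__all__ = [
    "DielWindows",
    "filter_events",
    "beam_height",
    "assign_layer",
    "assign_time_class",
    "build_event_table",
]

LAYERS = ("shrub", "canopy", "sky")
TIME_CLASSES = ("dawn", "diurnal", "dusk", "nocturnal")

#: Layer boundaries in meters, half-open lower-inclusive:
#: height < 2.5 -> shrub, 2.5 <= height < 25 -> canopy, height >= 25 -> sky.
SHRUB_CANOPY_M = 2.5
CANOPY_SKY_M = 25.0

#: Default instrument height: puts the 0-degree transect inside the
#: 1.5-2.5 m shrub band.
DEFAULT_H0_M = 1.8


@dataclass(frozen=True)
class DielWindows:
    """Dawn and dusk windows in local decimal hours, [start, end).

    Defaults bracket twilight at a near-equatorial site: dawn 05:30-07:30,
    dusk 17:30-19:30. Between dawn end and dusk start is diurnal; the rest
    of the clock is nocturnal.
    """

    dawn: tuple[float, float] = (5.5, 7.5)
    dusk: tuple[float, float] = (17.5, 19.5)

    def __post_init__(self):
        d0, d1 = self.dawn
        k0, k1 = self.dusk
        if not (0 <= d0 < d1 <= k0 < k1 <= 24):
            raise ValueError(
                "diel windows must satisfy 0 <= dawn_start < dawn_end <= "
                f"dusk_start < dusk_end <= 24, got dawn={self.dawn}, dusk={self.dusk}"
            )


def filter_events(
    events: list[TransitSignal],
    min_duration_ms: float = 25.0,
    min_samples: int = 80,
) -> list[TransitSignal]:
    """Observation-selection filter, order-preserving and idempotent.

    Keeps events with duration strictly exceeding ``min_duration_ms`` AND at
    least ``min_samples`` time samples.
    """
    if min_duration_ms <= 0 or min_samples <= 0:
        raise ValueError("thresholds must be > 0")
    return [
        ev
        for ev in events
        if ev.duration_ms > min_duration_ms and ev.n_samples >= min_samples
    ]


def beam_height(range_m: float, elevation_deg: float, h0_m: float = DEFAULT_H0_M) -> float:
    """Beam height above ground at a given range: h0 + range * sin(elevation)."""
    if np.any(np.asarray(range_m) < 0):
        raise ValueError("range_m must be >= 0")
    return h0_m + range_m * np.sin(np.radians(elevation_deg))


def assign_layer(height_m: float) -> str:
    """Vertical layer of a height (half-open, lower-inclusive boundaries).

    Heights below the nominal 1.5 m shrub floor are still labeled shrub:
    the three-way partition is exhaustive.
    """
    h = float(height_m)
    if not math.isfinite(h):
        raise ValueError(f"height must be finite, got {height_m}")
    if h < SHRUB_CANOPY_M:
        return "shrub"
    if h < CANOPY_SKY_M:
        return "canopy"
    return "sky"


def assign_time_class(t0: float, windows: DielWindows | None = None) -> str:
    """Diel time class of a timestamp (local-clock seconds or datetime64)."""
    if windows is None:
        windows = DielWindows()
    if isinstance(t0, (np.datetime64, pd.Timestamp)):
        ts = pd.Timestamp(t0)
        hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0
    else:
        hour = (float(t0) % 86400.0) / 3600.0
    d0, d1 = windows.dawn
    k0, k1 = windows.dusk
    if d0 <= hour < d1:
        return "dawn"
    if k0 <= hour < k1:
        return "dusk"
    if d1 <= hour < k0:
        return "diurnal"
    return "nocturnal"


def build_event_table(
    events: list[TransitSignal],
    windows: DielWindows | None = None,
    h0_m: float = DEFAULT_H0_M,
    start: np.datetime64 | None = None,
) -> pd.DataFrame:
    """Tabulate events with derived ecological labels.

    One row per event: identifiers, timing, geometry, derived height, layer
    and time class, plus empty feature columns (wbf_hz, depol, spectrum_id)
    filled in by the feature stage. ``start`` anchors t0 seconds to absolute
    timestamps for the t0 column; without it t0 stays in seconds.
    """
    rows = []
    for ev in events:
        h = beam_height(ev.range_m, ev.elevation_deg, h0_m)
        truth = ev.truth or {}
        rows.append(
            {
                "event_id": ev.event_id,
                "t0": (
                    pd.Timestamp(start) + pd.Timedelta(seconds=ev.t0)
                    if start is not None
                    else ev.t0
                ),
                "range_m": ev.range_m,
                "elevation_deg": ev.elevation_deg,
                "n_samples": ev.n_samples,
                "duration_ms": ev.duration_ms,
                "height_m": h,
                "layer": assign_layer(h),
                "time_class": assign_time_class(ev.t0, windows),
                "wbf_hz": np.nan,
                "depol": np.nan,
                "spectrum_id": "",
                "true_class": truth.get("class_id", ""),
                "true_wbf_hz": truth.get("wbf_true", np.nan),
            }
        )
    cols = [
        "event_id", "t0", "range_m", "elevation_deg", "n_samples", "duration_ms",
        "height_m", "layer", "time_class", "wbf_hz", "depol", "spectrum_id",
        "true_class", "true_wbf_hz",
    ]
    return pd.DataFrame(rows, columns=cols)
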