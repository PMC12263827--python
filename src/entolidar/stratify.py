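"""Ecological summaries: diel activity, ternary composition, per-cell diversity.

Raw event counts understate activity whenever the instrument was paused, so
activity is reported as a *compensated* rate: counts per time bin divided by
the fraction of the bin the instrument was actually recording. Bins with
almost no recording effort are reported as missing, not zero — a gap is
absent effort, not absent insects.

Cluster compositions (layer fractions, time-class fractions) live on a
3-simplex and are plotted in ternary diagrams; the temporal ternary merges
dawn and dusk into a crepuscular corner. Diversity consistency is assessed by
running the full clustering independently in every (day, layer) cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import diversity_pipeline
from .events import LAYERS
from .synthetic import SurveySchedule, operational_mask

__all__ = [
    "ActivitySeries",
    "activity_series",
    "daily_profile",
    "ternary_coords",
    "layer_day_diversity",
]


@dataclass(eq=False)
class ActivitySeries:
    """Per-bin activity of one layer, compensated for observation effort.

    ``compensated_rate`` is NaN (undefined) where the operational fraction
    falls below ``min_fraction`` — no data, as opposed to no activity.
    """

    layer: str
    bin_start_s: np.ndarray = field(repr=False)
    raw_count: np.ndarray = field(repr=False)
    operational_fraction: np.ndarray = field(repr=False)
    compensated_rate: np.ndarray = field(repr=False)
    bin_width_s: float = 600.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_s": self.bin_start_s,
                "raw_count": self.raw_count,
                "operational_fraction": self.operational_fraction,
                "compensated_rate": self.compensated_rate,
            }
        )


def activity_series(
    events: pd.DataFrame,
    schedule: SurveySchedule,
    layer: str,
    bin_width_s: float = 600.0,
    min_fraction: float = 0.1,
) -> ActivitySeries:
    """Observation-effort-compensated activity of one layer.

    Counts the layer's events in ``bin_width_s`` bins (default 10 min) over
    the survey span and divides each count by the bin's operational
    fraction from the schedule mask. ``events`` needs columns ``layer`` and
    ``t0_s`` (seconds from schedule start) or ``t0``.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be > 0")
    total = schedule.total_seconds
    n_bins = int(math.ceil(total / bin_width_s))
    edges = np.arange(n_bins + 1) * bin_width_s

    t0 = _t0_seconds(events, schedule)
    sel = events["layer"].to_numpy() == layer
    counts, _ = np.histogram(t0[sel], bins=edges)

    res = min(bin_width_s / 10.0, 10.0)
    mask, _ = operational_mask(schedule, res)
    t_grid = (np.arange(len(mask)) + 0.5) * res
    frac = np.zeros(n_bins)
    idx = np.minimum((t_grid // bin_width_s).astype(int), n_bins - 1)
    np.add.at(frac, idx, mask.astype(float))
    per_bin = np.bincount(idx, minlength=n_bins).astype(float)
    frac = np.divide(frac, per_bin, out=np.zeros(n_bins), where=per_bin > 0)

    rate = np.where(frac >= min_fraction, counts / np.where(frac > 0, frac, 1.0), np.nan)
    return ActivitySeries(
        layer=layer,
        bin_start_s=edges[:-1],
        raw_count=counts,
        operational_fraction=frac,
        compensated_rate=rate,
        bin_width_s=bin_width_s,
    )


def _t0_seconds(events: pd.DataFrame, schedule: SurveySchedule) -> np.ndarray:
    if "t0_s" in events.columns:
        return events["t0_s"].to_numpy(dtype=float)
    t0 = events["t0"]
    if pd.api.types.is_datetime64_any_dtype(t0):
        return (
            (t0 - pd.Timestamp(schedule.start)) / pd.Timedelta(seconds=1)
        ).to_numpy(dtype=float)
    return t0.to_numpy(dtype=float)


def daily_profile(series: ActivitySeries, day_length_s: float = 86400.0) -> pd.DataFrame:
    """Across-day mean and standard deviation per time-of-day bin.

    Folds the activity series onto the 24-h clock; undefined bins are
    excluded pairwise. The sd is the sample standard deviation over days
    (0 where only one day is defined).
    """
    tod = series.bin_start_s % day_length_s
    df = pd.DataFrame({"tod_s": tod, "rate": series.compensated_rate}).dropna()
    if df.empty:
        return pd.DataFrame(columns=["tod_s", "mean_rate", "sd_rate", "n_days"])
    g = df.groupby("tod_s")["rate"]
    out = pd.DataFrame(
        {
            "mean_rate": g.mean(),
            "sd_rate": g.std(ddof=1).fillna(0.0),
            "n_days": g.count(),
        }
    ).reset_index()
    return out


def ternary_coords(fractions) -> tuple[float, float]:
    """Planar coordinates of a 3-part composition in the unit triangle.

    With corner order (c1, c2, c3): x = c2 + c3/2, y = (sqrt(3)/2) * c3.
    The corners map to (0,0), (1,0) and (1/2, sqrt(3)/2). Nonnegative
    inputs are renormalized to sum 1.
    """
    f = np.asarray(fractions, dtype=float)
    if f.shape != (3,) or np.any(f < 0):
        raise ValueError("fractions must be 3 nonnegative values")
    s = f.sum()
    if s == 0:
        raise ValueError("fractions must not all be zero")
    c1, c2, c3 = f / s
    return float(c2 + c3 / 2.0), float(math.sqrt(3.0) / 2.0 * c3)


def layer_day_diversity(
    events: pd.DataFrame,
    spectra: dict[str, "ModulationSpectrum"],
    noise_spectra=None,
    schedule: SurveySchedule | None = None,
    min_events: int = 3,
    linkage_method: str = "single",
    beta_method: str = "median",
    detrend_order: str = "rank_desc",
) -> pd.DataFrame:
    """Independent diversity estimates per (day, layer) cell.

    Days split at local midnight. Each cell with at least ``min_events``
    events gets its own full clustering run (no state shared across cells);
    smaller cells report NoC as missing. Returns a long table with columns
    day, layer, n_events, noc; per-layer mean and sd across days are
    obtainable by a groupby on the result.
    """
    t0 = _t0_seconds(events, schedule) if schedule is not None else events["t0_s"].to_numpy()
    day = (t0 // 86400.0).astype(int)
    rows = []
    for d in np.unique(day):
        for layer in LAYERS:
            sel = (day == d) & (events["layer"].to_numpy() == layer)
            ids = events.loc[sel, "event_id"]
            cell = [spectra[i] for i in ids if i in spectra]
            if len(cell) >= min_events:
                res = diversity_pipeline(
                    cell,
                    noise_spectra,
                    linkage_method=linkage_method,
                    beta_method=beta_method,
                    detrend_order=detrend_order,
                )
                noc = res.noc
            else:
                noc = np.nan
            rows.append({"day": int(d), "layer": layer, "n_events": len(cell), "noc": noc})
    return pd.DataFrame(rows)


def layer_noc_consistency(table: pd.DataFrame) -> pd.DataFrame:
    """Per-layer mean and sd of NoC across days (the consistency summary)."""
    g = table.dropna(subset=["noc"]).groupby("layer")["noc"]
    return pd.DataFrame(
        {"mean_noc": g.mean(), "sd_noc": g.std(ddof=1).fillna(0.0), "n_days": g.count()}
    ).reset_index()
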