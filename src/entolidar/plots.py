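"""Report figures: diel activity, ternary compositions, per-cell diversity."""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stratify import ActivitySeries, daily_profile

__all__ = ["plot_activity", "plot_ternary", "plot_diversity_cells"]

_LAYER_COLORS = {"shrub": "tab:red", "canopy": "tab:green", "sky": "tab:blue"}


def plot_activity(series: dict[str, ActivitySeries], path: str | Path) -> None:
    """Mean +/- sd compensated activity per 10-min time-of-day bin, one panel per layer."""
    fig, axes = plt.subplots(len(series), 1, figsize=(8, 2.4 * len(series)), sharex=True)
    if len(series) == 1:
        axes = [axes]
    for ax, (layer, s) in zip(axes, series.items()):
        prof = daily_profile(s)
        if not prof.empty:
            h = prof["tod_s"] / 3600.0
            ax.plot(h, prof["mean_rate"], color=_LAYER_COLORS.get(layer, "k"), lw=1.2)
            ax.fill_between(
                h,
                prof["mean_rate"] - prof["sd_rate"],
                prof["mean_rate"] + prof["sd_rate"],
                alpha=0.3,
                color=_LAYER_COLORS.get(layer, "k"),
            )
        ax.set_ylabel("events / bin")
        ax.set_title(f"{layer} layer", fontsize=9)
    axes[-1].set_xlabel("local time [h]")
    axes[-1].set_xlim(0, 24)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _triangle(ax, labels):
    v = np.array([[0, 0], [1, 0], [0.5, math.sqrt(3) / 2], [0, 0]])
    ax.plot(v[:, 0], v[:, 1], "k-", lw=1)
    ax.text(-0.02, -0.04, labels[0], ha="right", fontsize=9)
    ax.text(1.02, -0.04, labels[1], ha="left", fontsize=9)
    ax.text(0.5, math.sqrt(3) / 2 + 0.03, labels[2], ha="center", fontsize=9)
    ax.set_aspect("equal")
    ax.axis("off")


def plot_ternary(
    df: pd.DataFrame,
    corner_labels: tuple[str, str, str],
    path: str | Path,
    cols: tuple[str, str, str] = ("shrub", "canopy", "sky"),
) -> None:
    """Cluster compositions in the unit triangle; dot area ~ sqrt(cluster size)."""
    fig, ax = plt.subplots(figsize=(5, 4.6))
    _triangle(ax, corner_labels)
    if len(df):
        size = 40 * np.sqrt(df["n"].to_numpy(dtype=float))
        ax.scatter(
            df["x"], df["y"], s=size, c=df["cluster"], cmap="turbo",
            alpha=0.75, edgecolors="k", linewidths=0.4,
        )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_diversity_cells(cells: pd.DataFrame, path: str | Path) -> None:
    """NoC per (day, layer) cell: layer sets hue, day sets brightness."""
    fig, ax = plt.subplots(figsize=(6, 4))
    days = sorted(cells["day"].unique())
    for i, layer in enumerate(("shrub", "canopy", "sky")):
        sub = cells[cells["layer"] == layer]
        base = _LAYER_COLORS[layer]
        for j, d in enumerate(days):
            row = sub[sub["day"] == d]
            if row.empty or row["noc"].isna().all():
                continue
            shade = 0.45 + 0.5 * j / max(len(days) - 1, 1)
            ax.scatter(
                [i + 0.15 * (j - (len(days) - 1) / 2)], row["noc"],
                color=base, alpha=shade, s=60, edgecolors="k", linewidths=0.4,
                label=f"{layer} d{d}" if i == 0 or True else None,
            )
    ax.set_xticks(range(3), ["shrub", "canopy", "sky"])
    ax.set_ylabel("NoC")
    ax.set_title("Diversity per layer across days", fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
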