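"""File formats: HDF5 signal containers, TSV tables, JSON results.

Signals live in one HDF5 file with a group per event (datasets ``co`` and
``de``, scalar attributes for timing, geometry and synthetic ground truth)
and a parallel ``noise/`` group for the negative-control fragments. Tables
are UTF-8 TSV with ISO-8601 timestamps and ``NA`` for undefined values;
cluster results are JSON. Every writer embeds the config hash and package
version.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .spectral import ModulationSpectrum, make_grid
from .synthetic import TransitSignal

__all__ = [
    "write_signals",
    "read_signals",
    "write_events_tsv",
    "read_events_tsv",
    "write_spectra",
    "read_spectra",
    "write_json",
]

_TRUTH_KEYS = ("class_id", "wbf_true", "duration_ms")


def _write_group(grp: h5py.Group, ev: TransitSignal) -> None:
    g = grp.create_group(ev.event_id)
    g.create_dataset("co", data=ev.co)
    g.create_dataset("de", data=ev.de)
    g.attrs["t0_s"] = ev.t0
    g.attrs["dt"] = ev.dt
    g.attrs["range_m"] = ev.range_m
    g.attrs["elevation_deg"] = ev.elevation_deg
    for k in _TRUTH_KEYS:
        if ev.truth and k in ev.truth:
            g.attrs[f"truth_{k}"] = ev.truth[k]


def _read_group(g: h5py.Group, event_id: str) -> TransitSignal:
    truth = {
        k: g.attrs[f"truth_{k}"] for k in _TRUTH_KEYS if f"truth_{k}" in g.attrs
    }
    if "class_id" in truth and isinstance(truth["class_id"], bytes):
        truth["class_id"] = truth["class_id"].decode()
    return TransitSignal(
        event_id=event_id,
        t0=float(g.attrs["t0_s"]),
        dt=float(g.attrs["dt"]),
        co=g["co"][...],
        de=g["de"][...],
        range_m=float(g.attrs["range_m"]),
        elevation_deg=float(g.attrs["elevation_deg"]),
        truth=truth or None,
    )


def write_signals(
    path: str | Path,
    events: list[TransitSignal],
    noise: list[TransitSignal] | None = None,
    meta: dict | None = None,
) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["entolidar_version"] = __version__
        for k, v in (meta or {}).items():
            fh.attrs[k] = v
        eg = fh.create_group("events")
        for ev in events:
            _write_group(eg, ev)
        ng = fh.create_group("noise")
        for ev in noise or []:
            _write_group(ng, ev)


def read_signals(path: str | Path) -> tuple[list[TransitSignal], list[TransitSignal]]:
    events, noise = [], []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh["events"]):
            events.append(_read_group(fh["events"][name], name))
        if "noise" in fh:
            for name in sorted(fh["noise"]):
                noise.append(_read_group(fh["noise"][name], name))
    return events, noise


def write_events_tsv(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Events table as TSV; a `# key: value` comment header carries metadata."""
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    if "t0" in df.columns and df["t0"].dtype == object:
        df["t0"] = pd.to_datetime(df["t0"])
    return df


def write_spectra(
    path_tsv: str | Path,
    spectra: list[ModulationSpectrum],
    meta: dict | None = None,
) -> None:
    """Spectra matrix as TSV (rows = events, columns = bin centers in Hz)
    plus a JSON sidecar recording the grid and channel mode."""
    if not spectra:
        raise ValueError("no spectra to write")
    grid = spectra[0].grid
    cols = [f"{c:.6g}" for c in grid.centers]
    df = pd.DataFrame(
        np.vstack([s.P for s in spectra]),
        index=[s.spectrum_id for s in spectra],
        columns=cols,
    )
    df.index.name = "spectrum_id"
    df.to_csv(path_tsv, sep="\t")
    sidecar = {
        "n_bins": grid.n_bins,
        "f_lo": grid.f_lo,
        "f_hi": grid.f_hi,
        "channel_mode": spectra[0].channel_mode,
        "entolidar_version": __version__,
        **(meta or {}),
    }
    Path(str(path_tsv) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_spectra(path_tsv: str | Path) -> list[ModulationSpectrum]:
    sidecar = json.loads(Path(str(path_tsv) + ".json").read_text())
    grid = make_grid(sidecar["f_lo"], sidecar["f_hi"], sidecar["n_bins"])
    df = pd.read_csv(path_tsv, sep="\t", index_col="spectrum_id")
    return [
        ModulationSpectrum(
            spectrum_id=str(idx),
            P=row.to_numpy(dtype=float),
            grid=grid,
            channel_mode=sidecar["channel_mode"],
        )
        for idx, row in df.iterrows()
    ]


def _jsonable(o):
    if isinstance(o, dict):
        return {k: _jsonable(v) for k, v in o.items()}
    if isinstance(o, (list, tuple)):
        return [_jsonable(v) for v in o]
    if isinstance(o, np.ndarray):
        return [_jsonable(v) for v in o.tolist()]
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, (float, np.floating)):
        f = float(o)
        return f if np.isfinite(f) else None  # NaN/inf -> null (undefined)
    return o


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, allow_nan=False))
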