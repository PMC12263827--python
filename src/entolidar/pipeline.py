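"""Stage orchestration: simulate -> features -> cluster -> stratify.

Each stage is a plain function over files plus a :class:`RunConfig`; the CLI
is a thin wrapper. Stage boundaries log the observation funnel (generated /
accepted / clustered counts) so selection effects stay visible.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, save_config
from .diversity import diversity_pipeline, summarize_clusters
from .events import DielWindows, build_event_table, filter_events
from .io import (
    read_events_tsv,
    read_signals,
    read_spectra,
    write_events_tsv,
    write_json,
    write_signals,
    write_spectra,
)
from .spectral import depolarization, estimate_wbf, make_grid, modulation_spectrum
from .stratify import (
    activity_series,
    daily_profile,
    layer_day_diversity,
    layer_noc_consistency,
    ternary_coords,
)
from .synthetic import (
    build_class_library,
    build_schedule,
    generate_noise_fragments,
    reference_wing_templates,
    sample_events,
)

log = logging.getLogger("entolidar")

__all__ = ["run_simulate", "run_features", "run_cluster", "run_stratify", "run_all"]


def _schedule(cfg: RunConfig):
    return build_schedule(
        start=np.datetime64(cfg.schedule_start),
        days=cfg.days,
        elevation_cycle=cfg.elevation_cycle,
        dwell_s=cfg.dwell_s,
        repositioning_pause_s=cfg.repositioning_pause_s,
        refuels_per_day=cfg.refuels_per_day,
        refuel_duration_s=cfg.refuel_duration_s,
    )


def _library(cfg: RunConfig):
    if cfg.library == "reference":
        return reference_wing_templates()
    if cfg.library == "generated":
        return build_class_library(cfg.n_classes, seed=cfg.seed, separation=cfg.separation)
    raise ValueError(f"unknown library kind {cfg.library!r}")


def _meta(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.hash, "entolidar_version": __version__}


def run_simulate(cfg: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Generate the synthetic survey: signals HDF5, events TSV, schedule TSV."""
    cfg.validate()
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    schedule = _schedule(cfg)
    library = _library(cfg)
    events = sample_events(
        library, schedule, base_rate=cfg.base_rate_per_hour, seed=cfg.seed,
        noise_sd=cfg.noise_sd, dt=cfg.dt, h0_m=cfg.h0_m,
    )
    noise = generate_noise_fragments(
        cfg.n_noise_fragments, noise_model=cfg.noise_model, seed=cfg.seed + 1, dt=cfg.dt
    )
    log.info(
        "simulate: %d events, %d noise fragments, duty fraction %.4f",
        len(events), len(noise), schedule.duty_fraction,
    )

    write_signals(out / "signals.h5", events, noise, meta=_meta(cfg))
    table = build_event_table(
        events,
        windows=DielWindows(cfg.dawn, cfg.dusk),
        h0_m=cfg.h0_m,
        start=schedule.start,
    )
    table.insert(2, "t0_s", [ev.t0 for ev in events])
    write_events_tsv(table, out / "events.tsv", meta=_meta(cfg))

    sched_rows = pd.DataFrame(
        schedule.operational_intervals, columns=["start_s", "end_s", "elevation_deg"]
    )
    write_events_tsv(
        sched_rows, out / "schedule.tsv",
        meta={**_meta(cfg), "duty_fraction": f"{schedule.duty_fraction:.6f}"},
    )
    save_config(cfg, out / "config.yaml")
    return out


def run_features(cfg: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Apply the selection filter and compute spectra, wingbeat and depolarization."""
    out = Path(out_dir or cfg.out_dir)
    events, noise = read_signals(out / "signals.h5")
    table = read_events_tsv(out / "events.tsv")

    accepted = filter_events(events, cfg.min_duration_ms, cfg.min_samples)
    rejected = {e.event_id for e in events} - {e.event_id for e in accepted}
    for rid in sorted(rejected):
        log.debug("features: rejected %s (duration/samples below threshold)", rid)
    log.info("features: %d events generated, %d accepted, %d rejected",
             len(events), len(accepted), len(rejected))

    grid = make_grid(cfg.f_lo, cfg.f_hi, cfg.n_bins)
    spectra, feats = [], {}
    for ev in accepted:
        spec = modulation_spectrum(
            ev, grid, cfg.detrend_window_ms, cfg.channel_mode, bin_mode=cfg.bin_mode
        )
        spectra.append(spec)
        feats[ev.event_id] = (
            estimate_wbf(ev, cfg.f_lo, cfg.f_hi, detrend_window_ms=cfg.detrend_window_ms),
            depolarization(ev, cfg.f_lo, cfg.f_hi, cfg.detrend_window_ms),
        )
    noise_accepted = filter_events(noise, cfg.min_duration_ms, cfg.min_samples)
    noise_spectra = [
        modulation_spectrum(ev, grid, cfg.detrend_window_ms, cfg.channel_mode, bin_mode=cfg.bin_mode)
        for ev in noise_accepted
    ]

    keep = table["event_id"].isin({e.event_id for e in accepted})
    table = table[keep].reset_index(drop=True)
    table["wbf_hz"] = [
        feats[i][0] if feats[i][0] is not None else np.nan for i in table["event_id"]
    ]
    table["depol"] = [
        feats[i][1] if feats[i][1] is not None else np.nan for i in table["event_id"]
    ]
    table["spectrum_id"] = table["event_id"]

    write_spectra(out / "spectra.tsv", spectra, meta={"config_hash": cfg.hash})
    if noise_spectra:
        write_spectra(out / "noise_spectra.tsv", noise_spectra, meta={"config_hash": cfg.hash})
    write_events_tsv(table, out / "events.tsv", meta=_meta(cfg))
    return out


def run_cluster(cfg: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Cluster the spectra and write the diversity result + labeled events."""
    out = Path(out_dir or cfg.out_dir)
    spectra = read_spectra(out / "spectra.tsv")
    noise_path = out / "noise_spectra.tsv"
    noise_spectra = read_spectra(noise_path) if noise_path.exists() else None
    table = read_events_tsv(out / "events.tsv")

    res = diversity_pipeline(
        spectra,
        noise_spectra,
        linkage_method=cfg.linkage_method,
        beta_method=cfg.beta_method,
        detrend_order=cfg.detrend_order,
    )
    log.info("cluster: N=%d, NoC=%d, beta=%.3f, noise NoC=%s",
             res.n_obs, res.noc, res.beta, res.noise_noc)

    order = {s.spectrum_id: i for i, s in enumerate(spectra)}
    table = table[table["spectrum_id"].isin(order)].reset_index(drop=True)
    table["cluster"] = [res.labels[order[s]] for s in table["spectrum_id"]]
    summaries = summarize_clusters(
        table["cluster"].to_numpy(), table, [spectra[order[s]] for s in table["spectrum_id"]]
    )
    for s in summaries:
        s.pop("mean_log_spectrum")

    write_json(
        {
            "NoC": res.noc,
            "beta": res.beta,
            "threshold": res.threshold,
            "noise_NoC": res.noise_noc,
            "n_observations": res.n_obs,
            "quantile_method": "linear",
            "linkage_method": res.linkage_method,
            "beta_method": res.beta_method,
            "detrend_order": res.detrend_order,
            "clusters": summaries,
            **_meta(cfg),
        },
        out / "clusters.json",
    )
    write_events_tsv(table, out / "events.tsv", meta=_meta(cfg))
    return out


def run_stratify(cfg: RunConfig, out_dir: str | Path | None = None, figures: bool = True) -> Path:
    """Write activity, ternary and per-(day, layer) diversity tables and figures."""
    out = Path(out_dir or cfg.out_dir)
    report = out / "report"
    report.mkdir(exist_ok=True)
    schedule = _schedule(cfg)
    table = read_events_tsv(out / "events.tsv")
    spectra = {s.spectrum_id: s for s in read_spectra(out / "spectra.tsv")}
    noise_path = out / "noise_spectra.tsv"
    noise_spectra = read_spectra(noise_path) if noise_path.exists() else None

    series = {}
    for layer in ("shrub", "canopy", "sky"):
        s = activity_series(table, schedule, layer, cfg.bin_width_s, cfg.min_fraction)
        series[layer] = s
        write_events_tsv(s.to_frame(), report / f"activity_{layer}.tsv", meta=_meta(cfg))
        prof = daily_profile(s)
        write_events_tsv(prof, report / f"daily_profile_{layer}.tsv", meta=_meta(cfg))
        log.info("stratify: activity_%s %d bins", layer, len(s.raw_count))

    # per-cluster ternary coordinates (spatial and temporal compositions)
    tern_rows_sp, tern_rows_tm = [], []
    for lab, sub in table.groupby("cluster"):
        n = len(sub)
        sp = [float((sub["layer"] == l).mean()) for l in ("shrub", "canopy", "sky")]
        crep = float(sub["time_class"].isin(["dawn", "dusk"]).mean())
        diu = float((sub["time_class"] == "diurnal").mean())
        noc_ = float((sub["time_class"] == "nocturnal").mean())
        x, y = ternary_coords(sp)
        tern_rows_sp.append(
            {"cluster": lab, "n": n, "shrub": sp[0], "canopy": sp[1], "sky": sp[2], "x": x, "y": y}
        )
        x, y = ternary_coords([crep, diu, noc_])
        tern_rows_tm.append(
            {"cluster": lab, "n": n, "crepuscular": crep, "diurnal": diu,
             "nocturnal": noc_, "x": x, "y": y}
        )
    tern_sp = pd.DataFrame(tern_rows_sp)
    tern_tm = pd.DataFrame(tern_rows_tm)
    write_events_tsv(tern_sp, report / "ternary_spatial.tsv", meta=_meta(cfg))
    write_events_tsv(tern_tm, report / "ternary_temporal.tsv", meta=_meta(cfg))

    cells = layer_day_diversity(
        table, spectra, noise_spectra, schedule=schedule,
        linkage_method=cfg.linkage_method, beta_method=cfg.beta_method,
        detrend_order=cfg.detrend_order,
    )
    write_events_tsv(cells, report / "diversity_by_day_layer.tsv", meta=_meta(cfg))
    consistency = layer_noc_consistency(cells)
    write_events_tsv(consistency, report / "diversity_consistency.tsv", meta=_meta(cfg))
    log.info("stratify: %d (day, layer) cells", len(cells))

    if figures:
        from .plots import plot_activity, plot_diversity_cells, plot_ternary

        plot_activity(series, report / "activity.png")
        plot_ternary(tern_sp, ("Shrub", "Canopy", "Open sky"), report / "ternary_spatial.png")
        plot_ternary(
            tern_tm, ("Crepuscular", "Diurnal", "Nocturnal"), report / "ternary_temporal.png",
            cols=("crepuscular", "diurnal", "nocturnal"),
        )
        plot_diversity_cells(cells, report / "diversity_by_day_layer.png")
    return report


def run_all(cfg: RunConfig, out_dir: str | Path | None = None, figures: bool = True) -> Path:
    """The full synthetic study end to end; deterministic for a fixed seed."""
    run_simulate(cfg, out_dir)
    run_features(cfg, out_dir)
    run_cluster(cfg, out_dir)
    return run_stratify(cfg, out_dir, figures=figures)
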