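"""Config-driven orchestration of the FRAP, SPT and co-localization stages.

Each item (cell, track, image pair) is processed independently: a failure is
recorded with its stage and input id and the remaining items continue. Every
run writes its tables plus a ``log.json`` recording package version,
parameters and seeds, so re-running an identical config on identical inputs
reproduces the deterministic outputs bit for bit.
"""

from __future__ import annotations

import platform
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import coloc as cl
from . import frap as fr
from . import spt
from .errors import OmdiffError, ParseError
from .io import (
    RunConfig,
    read_channel_pair,
    read_region_labels,
    read_stack,
    read_tracks,
    write_json,
)
from .spt import Track

__all__ = ["run_pipeline", "analyze_track_set", "analyze_frap_cells"]


def analyze_track_set(
    tracks: list[Track],
    *,
    immobile_threshold: float = spt.IMMOBILE_MSD_THRESHOLD_UM2,
    lag_window: tuple[float, float] = spt.CONFINEMENT_WINDOW_S,
    rho_threshold: float = spt.PLATEAU_RATIO_THRESHOLD,
) -> tuple[pd.DataFrame, list[dict]]:
    """Per-track SPT pipeline: filters, classification, D_2D, d_confine.

    Steps per track: duration >= 0.9 s; single-step photobleach check when
    an intensity trace is present (the track is trimmed at the detected
    change point before MSD); end-of-trajectory MSD > the immobility
    threshold; confined/brownian classification; mode-specific diffusion
    fit; confinement diameter for confined tracks.
    """
    columns = [
        "track_id", "n_frames", "duration_s", "bleach_ok", "retained",
        "plateau_um2", "mode", "d2d_um2_s", "intercept_um2", "d_confine_um", "flags",
    ]
    rows, errors = [], []
    for i, tr in enumerate(tracks):
        tid = tr.track_id if tr.track_id is not None else i
        try:
            row = {
                "track_id": tid, "n_frames": len(tr), "duration_s": tr.duration,
                "bleach_ok": None, "retained": False, "plateau_um2": np.nan,
                "mode": None, "d2d_um2_s": np.nan, "intercept_um2": np.nan,
                "d_confine_um": np.nan, "flags": "",
            }
            flags = []
            if tr.duration < spt.MIN_TRACK_DURATION_S - 1e-12:
                row["flags"] = "too_short"
                rows.append(row)
                continue
            work = tr
            if tr.intensity is not None and len(tr.intensity) >= 6:
                ok = spt.check_single_step_bleach(tr.intensity)
                row["bleach_ok"] = ok
                if not ok:
                    row["flags"] = "bleach_check_failed"
                    rows.append(row)
                    continue
                k, _, _ = spt.find_bleach_step(tr.intensity)
                if k >= 2 and k < len(tr):
                    work = Track(t=tr.t[:k], x=tr.x[:k], y=tr.y[:k], track_id=tid)
                if work.duration < spt.MIN_TRACK_DURATION_S - 1e-12:
                    row["flags"] = "too_short_after_bleach_trim"
                    rows.append(row)
                    continue
            curve = spt.compute_msd(work)
            plateau = spt.end_of_trajectory_msd(curve)
            row["plateau_um2"] = plateau
            if plateau <= immobile_threshold:
                row["flags"] = "immobile"
                rows.append(row)
                continue
            row["retained"] = True
            mode = spt.classify_mode(
                curve, window=lag_window, rho_threshold=rho_threshold
            )
            fit = spt.fit_diffusion(curve, mode)
            row.update(mode=mode, d2d_um2_s=fit.d2d, intercept_um2=fit.intercept)
            if fit.degenerate:
                flags.append("degenerate_fit")
            if mode == "confined":
                est = spt.confinement_diameter(curve, window=lag_window)
                row["d_confine_um"] = est.d_confine
            row["flags"] = ";".join(flags)
            rows.append(row)
        except OmdiffError as exc:
            errors.append({"stage": "spt", "input": str(tid), "error": str(exc)})
    return pd.DataFrame(rows, columns=columns), errors


def analyze_frap_cells(
    inputs: list[tuple], *, drift_correction: bool = True
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], list[dict]]:
    """Analyze (stack, sidecar[, labels]) path tuples into a results table.

    Returns (per-cell results, per-cell normalized curves, error records).
    """
    rows, curves, errors = [], {}, []
    for item in inputs:
        stack_path, sidecar_path = item[0], item[1]
        labels_path = item[2] if len(item) > 2 and item[2] else None
        cell_id = Path(stack_path).stem
        try:
            seq = read_stack(stack_path, sidecar_path)
            regions = read_region_labels(labels_path) if labels_path else None
            curve, mf = fr.analyze_sequence(
                seq, regions, drift_correction=drift_correction
            )
            rows.append(
                {
                    "cell_id": cell_id,
                    "i_postbleach": mf.i_postbleach,
                    "i_end": mf.i_end,
                    "mobile_fraction": mf.mobile_fraction,
                    "flags": ";".join(mf.flags),
                }
            )
            curves[cell_id] = pd.DataFrame({"t_s": curve.t, "i_hat": curve.i_hat})
        except OmdiffError as exc:
            errors.append({"stage": "frap", "input": cell_id, "error": str(exc)})
    frap_columns = ["cell_id", "i_postbleach", "i_end", "mobile_fraction", "flags"]
    return pd.DataFrame(rows, columns=frap_columns), curves, errors


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage and write all outputs under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"task": config.task, "errors": []}

    if config.task == "frap":
        results, curves, errors = analyze_frap_cells(
            [tuple(item) for item in config.frap_inputs]
        )
        results.to_csv(out / "frap_results.csv", index=False)
        for cell_id, cdf in curves.items():
            cdf.to_csv(out / f"curve_{cell_id}.csv", index=False)
        bundle.update(results=results, errors=errors)
    elif config.task == "tracks":
        if config.tracks_path is None:
            raise ParseError("task 'tracks' requires tracks_path")
        tracks = read_tracks(config.tracks_path)
        table, errors = analyze_track_set(
            tracks,
            immobile_threshold=config.immobile_threshold_um2,
            lag_window=config.lag_window_s,
            rho_threshold=config.rho_threshold,
        )
        table.to_csv(out / "track_results.csv", index=False)
        retained_ids = (
            set(table.loc[table["retained"], "track_id"]) if len(table) else set()
        )
        retained = [tr for tr in tracks if tr.track_id in retained_ids]
        if len(retained) >= 2:
            ens = spt.ensemble_msd(retained)
            pd.DataFrame(
                {"tau_s": ens.lags, "msd_um2": ens.msd, "sem": ens.sem, "n": ens.n_pairs}
            ).to_csv(out / "ensemble_msd.csv", index=False)
        bundle.update(results=table, errors=errors)
    elif config.task == "coloc":
        if config.image_a is None or config.image_b is None:
            raise ParseError("task 'coloc' requires image_a and image_b")
        pair = read_channel_pair(config.image_a, config.image_b, config.coloc_pixel_size_um)
        blurred = cl.ChannelPair(
            a=cl.blur(pair.a), b=cl.blur(pair.b), pixel_size_um=pair.pixel_size_um
        )
        mask = cl.make_analysis_mask(blurred)
        res = cl.pcc(blurred, mask)
        write_json(
            {"pcc": res.pcc, "n_mask_pixels": res.n_mask_pixels}, out / "pcc.json"
        )
        islands = cl.measure_islands(
            pair.a, config.coloc_pixel_size_um, config.min_island_um
        )
        pd.DataFrame(
            [(i.island_id, i.height_um, i.width_um) for i in islands],
            columns=["island_id", "height_um", "width_um"],
        ).to_csv(out / "islands_a.csv", index=False)
        bundle.update(pcc=res.pcc, n_mask_pixels=res.n_mask_pixels)
    else:
        raise ParseError(f"unknown task {config.task!r}")

    log = {
        "package": "omdiff",
        "version": __version__,
        "python": platform.python_version(),
        "config": {k: v for k, v in asdict(config).items()},
        "n_errors": len(bundle["errors"]),
    }
    write_json(log, out / "log.json")
    return bundle
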