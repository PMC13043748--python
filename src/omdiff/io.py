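"""Readers and writers for stacks, track tables, patch maps, and run configs.

Conventions fixed here for the whole package: track and mask coordinates are
physical µm with the origin at the top-left pixel center, pixel indices are
0-based, times and lags are seconds. The timestamp sidecar is authoritative
over any TIFF metadata. FRAP stacks are written as 16-bit multi-page TIFF
with a delimited sidecar (frame, t_s, phase); track tables are delimited
text with header ``track_id,frame,t_s,x_um,y_um,intensity``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .coloc import ChannelPair
from .errors import ParseError
from .frap import FrapSequence, RegionSet
from .spt import Track

__all__ = [
    "RunConfig",
    "write_stack",
    "read_stack",
    "write_tracks",
    "read_tracks",
    "write_patch_maps",
    "read_channel_pair",
    "read_region_labels",
]

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "intensity"]


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; defaults are the analysis constants in use.

    ``task`` selects the stage ('frap', 'tracks' or 'coloc'); the path
    fields feed it. The physical defaults (frame rate, immobile-MSD
    threshold 0.008 µm², lag window 0.5-0.8 s, plateau-ratio threshold 0.6,
    tracking pixel size 0.096 µm) are the constants the analyses assume.
    """

    task: str = "frap"
    out_dir: str = "omdiff_out"
    seed: int | None = None
    # FRAP inputs: list of (stack, sidecar[, mask]) path tuples
    frap_inputs: list = dataclasses.field(default_factory=list)
    # SPT inputs
    tracks_path: str | None = None
    frame_rate_hz: float = 30.0
    # coloc inputs
    image_a: str | None = None
    image_b: str | None = None
    # constants
    spt_pixel_size_um: float = 0.096
    immobile_threshold_um2: float = 0.008
    lag_window_s: tuple[float, float] = (0.5, 0.8)
    rho_threshold: float = 0.6
    coloc_pixel_size_um: float = 0.01
    min_island_um: float = 0.05

    def validate(self) -> None:
        if self.frame_rate_hz <= 0 or self.spt_pixel_size_um <= 0:
            raise ParseError("frame rate and pixel sizes must be positive")
        if self.immobile_threshold_um2 < 0 or self.rho_threshold <= 0:
            raise ParseError("thresholds must be positive")
        lo, hi = self.lag_window_s
        if not 0 < lo < hi:
            raise ParseError("lag window must satisfy 0 < lo < hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        if "lag_window_s" in raw:
            raw["lag_window_s"] = tuple(raw["lag_window_s"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def write_stack(seq: FrapSequence, tiff_path: str | Path, sidecar_path: str | Path) -> None:
    """Write a FRAP sequence as 16-bit multi-page TIFF plus timestamp sidecar.

    Frame values are rounded and clipped to the uint16 range.
    """
    frames = np.clip(np.round(seq.frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(tiff_path), frames, photometric="minisblack")
    pd.DataFrame(
        {"frame": np.arange(len(seq.t)), "t_s": seq.t, "phase": seq.phase}
    ).to_csv(sidecar_path, index=False)


def read_stack(tiff_path: str | Path, sidecar_path: str | Path) -> FrapSequence:
    """Read a stack + sidecar pair back into a :class:`FrapSequence`."""
    try:
        frames = tifffile.imread(str(tiff_path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"unreadable stack {tiff_path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None]
    side = pd.read_csv(sidecar_path)
    missing = {"frame", "t_s", "phase"} - set(side.columns)
    if missing:
        raise ParseError(f"sidecar missing columns {sorted(missing)}")
    if len(side) != frames.shape[0]:
        raise ParseError(
            f"frame count mismatch: stack has {frames.shape[0]} frames, "
            f"sidecar {len(side)} rows"
        )
    t = side["t_s"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ParseError("sidecar timestamps are not strictly increasing")
    return FrapSequence(
        frames=frames.astype(float),
        t=t,
        phase=side["phase"].to_numpy(dtype=object),
        meta={"source": str(tiff_path)},
    )


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write tracks as a delimited table with the standard header."""
    rows = []
    for i, tr in enumerate(tracks):
        tid = tr.track_id if tr.track_id is not None else i
        inten = tr.intensity if tr.intensity is not None else np.full(len(tr), np.nan)
        for k in range(len(tr)):
            rows.append((tid, k, tr.t[k], tr.x[k], tr.y[k], inten[k]))
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_tracks(path: str | Path) -> list[Track]:
    """Read a track table; groups by id, sorts by frame, validates sampling."""
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"track table missing columns {sorted(missing)}")
    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        if grp["frame"].duplicated().any():
            raise ParseError(f"track {tid!r}: duplicate (track, frame) pair")
        inten = grp["intensity"].to_numpy(dtype=float)
        track = Track(
            t=grp["t_s"].to_numpy(dtype=float),
            x=grp["x_um"].to_numpy(dtype=float),
            y=grp["y_um"].to_numpy(dtype=float),
            intensity=None if np.all(np.isnan(inten)) else inten,
            track_id=tid,
        )
        if len(track) >= 2:
            try:
                track.dt  # validates uniform sampling
            except Exception as exc:
                raise ParseError(str(exc)) from exc
        tracks.append(track)
    return tracks


def write_patch_maps(
    pair: ChannelPair,
    truth: dict,
    path_a: str | Path,
    path_b: str | Path,
    truth_path: str | Path,
) -> None:
    """Write the two channels as single-page TIFFs plus a ground-truth table."""
    tifffile.imwrite(str(path_a), pair.a.astype(np.float32))
    tifffile.imwrite(str(path_b), pair.b.astype(np.float32))
    rows = []
    for ch in ("a", "b"):
        centers = truth[f"centers_{ch}_um"]
        diams = truth[f"diameters_{ch}_um"]
        for (cx, cy), d in zip(centers, diams):
            rows.append((ch, cx, cy, d))
    pd.DataFrame(
        rows, columns=["channel", "center_x_um", "center_y_um", "diameter_um"]
    ).to_csv(truth_path, index=False)


def read_channel_pair(
    path_a: str | Path, path_b: str | Path, pixel_size_um: float
) -> ChannelPair:
    a = tifffile.imread(str(path_a))
    b = tifffile.imread(str(path_b))
    return ChannelPair(a=a, b=b, pixel_size_um=pixel_size_um)


def read_region_labels(path: str | Path) -> RegionSet:
    """Read a user-supplied label image: 0 background, 1 cell, 2 bleach."""
    lab = tifffile.imread(str(path))
    return RegionSet(
        bleach=lab == 2,
        cell=(lab == 1) | (lab == 2),
        background=lab == 0,
    )


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
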