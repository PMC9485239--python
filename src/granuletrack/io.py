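"""Readers and writers for the standard on-disk formats of the pipeline.

Movies are multi-page TIFF stacks (one file per channel), track tables
are CSV with documented headers (positions always in µm), region outlines
are JSON polygon files, configurations are YAML.  Readers validate rather
than silently convert: a missing column or a coordinate outside the
declared pixel grid is an error naming the offender.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from granuletrack.tracking import Track

__all__ = [
    "read_stack",
    "write_stack",
    "read_track_csv",
    "write_track_csv",
    "tracks_from_table",
    "read_polygons",
    "write_polygons",
    "read_config_yaml",
    "write_config_yaml",
    "write_masks",
]

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


def read_stack(path) -> np.ndarray:
    """Read a multi-page TIFF stack as (n_frames, ny, nx)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D image stack, got shape {arr.shape}")
    return arr


def write_stack(path, stack: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(stack), photometric="minisblack")


def write_masks(path, masks: np.ndarray) -> None:
    """Write boolean masks as a multi-page 8-bit TIFF (255 = inside)."""
    tifffile.imwrite(path, (np.asarray(masks, dtype=bool) * np.uint8(255)), photometric="minisblack")


def read_track_csv(path, extent_um: tuple[float, float] | None = None) -> pd.DataFrame:
    """Read a track table CSV; validates required columns and coordinates.

    Required columns: track_id, frame, x_um, y_um (positions in µm; a
    table with pixel-named columns is rejected rather than converted).
    """
    df = pd.read_csv(path)
    for col in TRACK_COLUMNS:
        if col not in df.columns:
            if col in ("x_um", "y_um") and col.replace("_um", "_px") in df.columns:
                raise ValueError(
                    f"{path}: found pixel-unit column {col.replace('_um', '_px')!r}; "
                    f"positions must be supplied in µm as {col!r}"
                )
            raise ValueError(f"{path}: missing required column {col!r}")
    bad = df[~np.isfinite(df[["x_um", "y_um"]]).all(axis=1)]
    if len(bad):
        raise ValueError(f"{path}: non-finite coordinates at rows {bad.index.tolist()[:5]}")
    if extent_um is not None:
        ex, ey = extent_um
        out = df[(df.x_um < 0) | (df.x_um > ex) | (df.y_um < 0) | (df.y_um > ey)]
        if len(out):
            raise ValueError(
                f"{path}: {len(out)} coordinates outside the declared pixel grid "
                f"(first offending row {out.index[0]})"
            )
    return df


def write_track_csv(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.6f")


def tracks_from_table(df: pd.DataFrame) -> list[Track]:
    """Build Track objects from a long-format table (with optional gap_after)."""
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        gaps = g["gap_after"].to_numpy()[:-1].astype(bool) if "gap_after" in g else None
        tracks.append(
            Track(
                track_id=int(tid),
                frames=g["frame"].to_numpy(),
                xy=g[["x_um", "y_um"]].to_numpy(),
                intensity=g["intensity"].to_numpy() if "intensity" in g else None,
                gap_after=gaps,
            )
        )
    return tracks


def read_polygons(path) -> dict[str, np.ndarray]:
    """Read a polygon JSON file ({"cell": [[x_um, y_um], ...], "nucleus": ...})."""
    data = json.loads(Path(path).read_text())
    out = {}
    for name, verts in data.items():
        if not isinstance(verts, list):
            continue
        arr = np.asarray(verts, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
            raise ValueError(f"{path}: polygon {name!r} needs >= 3 (x, y) vertices")
        out[name] = arr
    return out


def write_polygons(path, polygons: dict[str, np.ndarray]) -> None:
    Path(path).write_text(
        json.dumps({k: np.asarray(v).tolist() for k, v in polygons.items()}, indent=1)
    )


def convert_vendor_tracks(path) -> None:
    """Stub for the binary track archives of the original tracking software.

    Reading that Matlab-based format is out of scope; export the tracks to
    CSV with columns track_id, frame (0-based), x_um, y_um and optionally
    intensity and gap_after (0/1), then use :func:`read_track_csv`.
    """
    raise NotImplementedError(
        "binary vendor track formats are not read; export a CSV with columns "
        "track_id, frame, x_um, y_um [, intensity, gap_after] instead"
    )


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_config_yaml(path, config: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
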