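"""Self-describing CSV/TIFF I/O for localization tables, tracks and movies.

Every CSV carries ``#``-prefixed header comments recording the schema
version, units and the parameters that produced it, so each pipeline
artifact explains itself. Coordinates are nm with the origin at the
top-left corner of pixel (0, 0); frames are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .localize import Trajectory
from .sim.render import ImageStack

SCHEMA_VERSION = "1"

__all__ = ["write_table", "read_table", "write_stack", "read_stack", "tracks_to_table"]


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """Write a CSV with commented schema/parameter header lines."""
    path = Path(path)
    meta = dict(meta or {})
    meta.setdefault("schema_version", SCHEMA_VERSION)
    meta.setdefault("units", "coordinates nm (origin: top-left corner of pixel 0,0); time s; frames 0-based")
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    """Read a commented CSV; returns (frame, metadata dict)."""
    path = Path(path)
    meta: dict = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, skiprows=skip)
    return df, meta


def tracks_to_table(tracks: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, x, y in zip(tr.frames, tr.x_nm, tr.y_nm):
            rows.append((tr.track_id, int(f), float(x), float(y), tr.sigma_nm))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_nm", "y_nm", "sigma_nm"])


def write_stack(stack: ImageStack, path: str | Path, interleaved: bool = False) -> None:
    """Write a movie as multi-page TIFF: one file per channel, or interleaved.

    Per-channel files get a ``_<channel>.tif`` suffix; interleaved mode
    writes one file with channels alternating within each frame.
    """
    path = Path(path)
    if interleaved:
        names = sorted(stack.channels)
        data = np.stack([stack.channels[ch] for ch in names], axis=1)
        tifffile.imwrite(
            path, data.astype(np.float32), photometric="minisblack",
            metadata={"channels": names, "pixel_size_nm": stack.pixel_size_nm},
        )
    else:
        for ch, arr in stack.channels.items():
            tifffile.imwrite(
                path.with_name(f"{path.stem}_{ch}.tif"), arr.astype(np.float32),
                photometric="minisblack",
                metadata={"channel": ch, "pixel_size_nm": stack.pixel_size_nm},
            )


def read_stack(path: str | Path) -> np.ndarray:
    """Read a (multi-page) TIFF movie as a float array."""
    return tifffile.imread(path).astype(float)
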