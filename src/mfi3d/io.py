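"""File I/O: multifocal TIFF stacks, track tables, configuration."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from mfi3d.frame import MultifocalFrame


def write_multifocal_tiff(
    path, frames: list[MultifocalFrame], tiled: bool = False
) -> None:
    """Write a time series of multifocal frames to TIFF.

    Stacked layout: one page per plane, ordered plane1..plane4 per timepoint.
    Tiled layout: one page per timepoint holding the 2x2 quadrant image.
    """
    if tiled:
        data = np.stack([f.to_tiled() for f in frames])
    else:
        data = np.concatenate([f.planes for f in frames])
    tifffile.imwrite(path, data.astype(np.float32), photometric="minisblack")


def read_multifocal_tiff(
    path,
    plane_offsets: np.ndarray,
    pixel_pitch: float,
    tiled: bool = False,
    frame_rate: float | None = None,
) -> list[MultifocalFrame]:
    """Read frames written by :func:`write_multifocal_tiff`."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    frames = []
    if tiled:
        for i, page in enumerate(data):
            ts = i / frame_rate if frame_rate else 0.0
            frames.append(
                MultifocalFrame.from_tiled(page, plane_offsets, pixel_pitch, ts)
            )
    else:
        if data.shape[0] % 4:
            raise ValueError("stacked TIFF page count must be a multiple of 4")
        for i in range(data.shape[0] // 4):
            ts = i / frame_rate if frame_rate else 0.0
            frames.append(
                MultifocalFrame(
                    data[4 * i : 4 * i + 4], plane_offsets, pixel_pitch, ts
                )
            )
    return frames


def tracks_to_dataframe(tracks, frame_rate: float = 500.0) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for frame, pos in zip(tr.frames, tr.positions):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": int(frame),
                    "t_s": frame / frame_rate,
                    "x_um": pos[0],
                    "y_um": pos[1],
                    "z_um": pos[2],
                }
            )
    return pd.DataFrame(rows)


def dataframe_to_tracks(df: pd.DataFrame):
    from mfi3d.bead3d import BeadTrack

    tracks = []
    for tid, group in df.groupby("track_id"):
        group = group.sort_values("frame")
        tracks.append(
            BeadTrack(
                int(tid),
                group["frame"].to_numpy(dtype=int),
                group[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            )
        )
    return tracks


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(path, config: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh)
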